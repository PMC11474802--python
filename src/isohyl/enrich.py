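"""Flanking-sequence motifs, secondary-structure depletion and generic ORA.

Modification sites are characterised three ways: a position-frequency
matrix over fixed-width flanking windows (for sequence-logo rendering), a
motif-x-style iterative motif search (binomial step p-values), and
hypergeometric tests — per secondary-structure class (helix/strand/turn)
against all lysines in the identified background, and as a generic
over-representation analysis over user-supplied annotation sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FlankWindow",
    "StructureAnnotation",
    "EnrichmentResult",
    "extract_flanks",
    "position_frequency_matrix",
    "motif_enrich",
    "structure_depletion",
    "ora",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"


@dataclass(frozen=True)
class FlankWindow:
    """A 2w+1 window centered on a modified residue, padded with '_'."""

    window: str
    protein: str
    position: int  # 1-based center position in the protein

    def __post_init__(self):
        if len(self.window) % 2 != 1:
            raise ValueError("window length must be odd")

    @property
    def center(self) -> str:
        return self.window[len(self.window) // 2]


@dataclass(frozen=True)
class StructureAnnotation:
    """Per-protein secondary-structure intervals, 1-based inclusive."""

    intervals: tuple[tuple[str, int, int, str], ...]  # (protein, start, end, kind)

    KINDS = ("HELIX", "STRAND", "TURN")

    def __post_init__(self):
        by_protein: dict[str, list[tuple[int, int]]] = {}
        for protein, start, end, kind in self.intervals:
            if kind not in self.KINDS:
                raise ValueError(f"unknown structure kind {kind!r}")
            if start > end:
                raise ValueError(f"interval start {start} > end {end}")
            for s, e in by_protein.get(protein, []):
                if start <= e and s <= end:
                    raise ValueError(
                        f"overlapping structure intervals on {protein}"
                    )
            by_protein.setdefault(protein, []).append((start, end))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StructureAnnotation":
        return cls(
            tuple(
                (str(r.protein), int(r.start), int(r.end), str(r.kind))
                for r in df.itertuples()
            )
        )

    def kind_at(self, protein: str, position: int) -> Optional[str]:
        for p, start, end, kind in self.intervals:
            if p == protein and start <= position <= end:
                return kind
        return None


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # foreground hits
    n: int  # foreground size
    K: int  # background hits
    N: int  # background size
    p: float
    q: float = np.nan
    direction: str = "enriched"

    def __post_init__(self):
        if not (self.k <= self.n and self.k <= self.K and self.K <= self.N
                and self.n <= self.N):
            raise ValueError("inconsistent contingency counts")


def extract_flanks(
    sites: Sequence[tuple[str, int]],
    proteome: Mapping[str, str],
    w: int = 6,
    require_center: Optional[str] = "K",
) -> list[FlankWindow]:
    """Fixed-width flanking windows around sites, padded at the termini."""
    if w < 1:
        raise ValueError("w must be >= 1")
    out = []
    for protein, pos in sites:
        seq = proteome.get(protein)
        if seq is None:
            raise KeyError(f"protein {protein!r} not in proteome")
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"site {protein}:{pos} outside protein of length {len(seq)}")
        center = seq[pos - 1]
        if require_center and center != require_center:
            raise ValueError(
                f"site {protein}:{pos} is {center}, expected {require_center}"
            )
        left = seq[max(0, pos - 1 - w) : pos - 1].rjust(w, PAD)
        right = seq[pos : pos + w].ljust(w, PAD)
        out.append(FlankWindow(left + center + right, protein, pos))
    return out


def position_frequency_matrix(windows: Sequence[FlankWindow]) -> pd.DataFrame:
    """Residue counts per window offset; rows are residues (+ '_' padding),
    columns are offsets -w..w relative to the modified residue."""
    if not windows:
        raise ValueError("no windows")
    length = len(windows[0].window)
    w = length // 2
    offsets = list(range(-w, w + 1))
    counts = pd.DataFrame(
        0, index=list(AMINO_ACIDS) + [PAD], columns=offsets, dtype=int
    )
    for win in windows:
        if len(win.window) != length:
            raise ValueError("windows of mixed width")
        for off, ch in zip(offsets, win.window):
            counts.loc[ch, off] += 1
    return counts


@dataclass(frozen=True)
class Motif:
    """An ordered set of fixed (offset, residue) constraints plus stats."""

    pattern: tuple[tuple[int, str], ...]
    n_foreground: int
    n_background: int
    fold: float
    score: float  # -log10 of the worst step p-value

    def as_string(self, w: int = 6) -> str:
        chars = ["."] * (2 * w + 1)
        chars[w] = "K"
        for off, res in self.pattern:
            chars[w + off] = res
        return "".join(chars)


def _matches(window: str, off: int, res: str, w: int) -> bool:
    return window[w + off] == res


def motif_enrich(
    foreground: Sequence[FlankWindow],
    background: Sequence[FlankWindow],
    p_threshold: float = 1e-6,
    min_support: int = 20,
    max_depth: int = 5,
) -> list[Motif]:
    """motif-x-style iterative motif extraction.

    Greedily fixes the (offset, residue) pair with the smallest binomial
    p-value given the windows matching the current motif, removes matching
    windows once a motif is complete, and repeats.  Deterministic:
    candidate ties break on (p, offset, residue).
    """
    if len(foreground) > len(background):
        raise ValueError("foreground larger than background")
    if not foreground:
        return []
    w = len(foreground[0].window) // 2
    fg = [x.window for x in foreground]
    bg = [x.window for x in background]
    motifs: list[Motif] = []
    while True:
        pattern: list[tuple[int, str]] = []
        cur_fg, cur_bg = list(fg), list(bg)
        worst_p = 0.0
        while True:
            best = None
            n_fg, n_bg = len(cur_fg), len(cur_bg)
            if n_fg < min_support or n_bg == 0:
                break
            for off in range(-w, w + 1):
                if off == 0 or any(o == off for o, _ in pattern):
                    continue
                for res in AMINO_ACIDS:
                    k = sum(1 for x in cur_fg if _matches(x, off, res, w))
                    if k < min_support:
                        continue
                    kb = sum(1 for x in cur_bg if _matches(x, off, res, w))
                    p_bg = kb / n_bg
                    if p_bg == 0 or k / n_fg <= p_bg:
                        continue
                    pval = float(stats.binom.sf(k - 1, n_fg, p_bg))
                    cand = (pval, off, res, k, kb)
                    if best is None or cand < best:
                        best = cand
            if best is None or best[0] > p_threshold:
                break
            pval, off, res, k, kb = best
            pattern.append((off, res))
            worst_p = max(worst_p, pval)
            cur_fg = [x for x in cur_fg if _matches(x, off, res, w)]
            cur_bg = [x for x in cur_bg if _matches(x, off, res, w)]
            if len(pattern) >= max_depth:
                break
        if not pattern:
            break
        fg_frac = len(cur_fg) / len(fg)
        bg_frac = len(cur_bg) / len(bg) if bg else 0.0
        motifs.append(
            Motif(
                pattern=tuple(sorted(pattern)),
                n_foreground=len(cur_fg),
                n_background=len(cur_bg),
                fold=(fg_frac / bg_frac) if bg_frac > 0 else np.inf,
                score=-np.log10(max(worst_p, 1e-300)),
            )
        )
        matched = set(cur_fg)
        fg = [x for x in fg if x not in matched]
        bg_matched = {
            x for x in bg if all(_matches(x, o, r, w) for o, r in pattern)
        }
        bg = [x for x in bg if x not in bg_matched]
        if len(fg) < min_support:
            break
    return motifs


def _hypergeom_directional(k: int, N: int, K: int, n: int) -> tuple[float, str]:
    """One-sided hypergeometric p in the observed direction."""
    rv = stats.hypergeom(N, K, n)
    expected = n * K / N
    if k < expected:
        return float(rv.cdf(k)), "depleted"
    return float(rv.sf(k - 1)), "enriched"


def structure_depletion(
    sites: Sequence[tuple[str, int]],
    background_lysines: Sequence[tuple[str, int]],
    annotation: StructureAnnotation,
) -> pd.DataFrame:
    """Fractions of sites vs background lysines per structure class, with
    a hypergeometric p in the observed direction for each class and for
    membership in any structure.

    Sites must be a subset of the background (the background is all
    lysines on identified peptides, which contains the modified ones).
    """
    bg = set(background_lysines)
    missing = [s for s in sites if s not in bg]
    if missing:
        raise ValueError(f"site(s) not in background: {missing[:3]}")
    N = len(bg)
    n = len(set(sites))
    classes = list(StructureAnnotation.KINDS) + ["ANY"]
    bg_kind = {s: annotation.kind_at(*s) for s in bg}
    rows = []
    for cls in classes:
        def in_class(site):
            kind = bg_kind[site]
            return kind is not None if cls == "ANY" else kind == cls

        K = sum(1 for s in bg if in_class(s))
        k = sum(1 for s in set(sites) if in_class(s))
        if K == 0:
            p, direction = 1.0, "enriched"
        else:
            p, direction = _hypergeom_directional(k, N, K, n)
        rows.append(
            {
                "class": cls,
                "site_fraction": k / n if n else np.nan,
                "background_fraction": K / N if N else np.nan,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": p,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def ora(
    foreground: Iterable[str],
    background: Iterable[str],
    annotation_sets: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation analysis with BH adjustment.

    ``annotation_sets`` maps a term to the ids it annotates (GMT-style).
    Results are sorted by (q, p, term).
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    fg = set(foreground) & bg
    results = []
    for term, members in annotation_sets.items():
        hits_bg = set(members) & bg
        K = len(hits_bg)
        k = len(hits_bg & fg)
        p = float(stats.hypergeom(len(bg), K, len(fg)).sf(k - 1))
        results.append(
            EnrichmentResult(term=term, k=k, n=len(fg), K=K, N=len(bg), p=p)
        )
    if results:
        qs = multipletests([r.p for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(r.term, r.k, r.n, r.K, r.N, r.p, q=float(q))
            for r, q in zip(results, qs)
        ]
    return sorted(results, key=lambda r: (r.q, r.p, r.term))


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT-like file: set-name <TAB> description <TAB> id..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out[parts[0]] = {p for p in parts[2:] if p}
    return out
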