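"""Seeded generators for every fixture the pipeline needs.

Emulates what the enrichment workflow produces from real samples: a
proteome with planted 5-Hyl sites, centroided LC-MS runs in which each
planted peptide elutes as a Gaussian MS1 peak in its three reaction forms
(unreacted / periodate-oxidized / methoxyamine-conjugated) with MS2 spectra
of the conjugated form, and two-condition site-intensity matrices with
planted log2 fold changes and per-sample spike-in areas.

Everything is driven by a single seed; identical configs give
byte-identical outputs.  Form fractions default to 6/24/70 percent of the
three-form total — the partition that yields 94% oxidation and 70%
conjugation efficiency, the working point of the chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import builtin_registry
from .peptides import DigestionParams, ModifiedPeptide, digest, parse_peptide
from .quant import SiteQuantMatrix
from .spectra import SearchParams, SpectrumRecord, theoretical_spectrum

__all__ = [
    "SimConfig",
    "make_proteome",
    "simulate_run",
    "simulate_quant",
    "collagen_peptide",
    "simulate_collagen_run",
]

# Approximate natural amino-acid frequencies (vertebrate proteomes).
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array(
    [8.3, 1.4, 5.5, 6.8, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7,
     2.4, 4.1, 6.3, 4.0, 5.7, 6.6, 5.4, 6.9, 1.1, 2.9]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic fixtures.

    Reaction-form fractions, noise levels and the two-condition design are
    the package's working defaults; see docs/methods.md for rationale.
    """

    seed: int
    # proteome
    n_proteins: int = 12
    protein_length: tuple[int, int] = (150, 300)
    sites_per_protein: int = 2
    motif_bias: float = 0.0  # probability of forcing P at the -1 flank
    # LC-MS run
    form_fractions: tuple[float, float, float] = (0.06, 0.24, 0.70)
    charge: int = 2
    peak_sigma_s: float = 3.0
    scan_interval_s: float = 1.0
    rt_spacing_s: float = 30.0
    # lock-mass-calibrated Orbitrap MS1 scans are reproducible to a few
    # tenths of a ppm; fragment m/z in MS2 is looser but far inside the
    # 0.5 Da matching tolerance either way
    ms1_jitter_ppm: float = 0.2
    fragment_jitter_ppm: float = 5.0
    fragment_dropout: float = 0.2
    noise_peaks: int = 30
    ms1_noise_peaks: int = 5
    ms2_per_peptide: int = 3
    base_intensity: float = 1e6
    # two-condition quantification
    n_per_group: int = 3
    frac_affected: float = 0.1
    log2_fc: float = 2.0  # mean of the planted log2 fold-change distribution
    log2_fc_sigma: float = 0.5  # spread of planted fold changes across sites
    residual_sigma: float = 0.25  # replicate noise after spike-in normalization
    spikein_sigma: float = 0.3

    def __post_init__(self):
        if abs(sum(self.form_fractions) - 1.0) > 1e-9:
            raise ValueError("form fractions must sum to 1")
        if not (0 <= self.motif_bias <= 1 and 0 <= self.fragment_dropout <= 1
                and 0 <= self.frac_affected <= 1):
            raise ValueError("probabilities must lie in [0,1]")


_SITE_DIGESTION = DigestionParams(
    max_missed_cleavages=6, min_length=7, max_length=30
)


def _containing_peptide(
    seq: str, pos: int, blocked: Sequence[int]
) -> Optional[tuple[int, int]]:
    """Smallest valid tryptic peptide covering a blocked (modified) site."""
    best = None
    for start, end, missed in digest(seq, _SITE_DIGESTION, blocked_positions=blocked):
        if start <= pos <= end and pos != end:  # modified K cannot be C-terminal
            if best is None or (end - start) < (best[1] - best[0]):
                best = (start, end)
    return best


def make_proteome(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Random proteome with planted 5-Hyl sites and its ground-truth table.

    Sites are planted only where the modified (cleavage-blocked) lysine
    sits on a well-formed tryptic peptide, so every truth row is in
    principle identifiable.  With ``motif_bias`` the -1 flank is set to
    proline to mimic a sequence preference of the writer enzyme.
    """
    rng = np.random.default_rng(config.seed)
    proteome: dict[str, str] = {}
    truth_rows = []
    for i in range(config.n_proteins):
        acc = f"SYN{i:04d}"
        length = int(rng.integers(config.protein_length[0], config.protein_length[1] + 1))
        seq = list(rng.choice(list(_AA), size=length, p=_AA_FREQ))
        k_positions = [j + 1 for j, r in enumerate(seq) if r == "K"]
        rng.shuffle(k_positions)
        planted: list[int] = []
        for pos in k_positions:
            if len(planted) >= config.sites_per_protein:
                break
            if pos == 1 or pos == length:
                continue
            trial = list(seq)
            if rng.random() < config.motif_bias:
                trial[pos - 2] = "P"
            span = _containing_peptide("".join(trial), pos, planted + [pos])
            if span is None:
                continue
            # re-check previously planted sites still sit on valid peptides
            ok = all(
                _containing_peptide("".join(trial), p, planted + [pos])
                for p in planted
            )
            if not ok:
                continue
            seq = trial
            planted.append(pos)
        proteome[acc] = "".join(seq)
        for pos in sorted(planted):
            truth_rows.append({"protein": acc, "position": pos})
    truth = pd.DataFrame(truth_rows, columns=["protein", "position"])
    return proteome, truth


# the three reaction forms of a 5-Hyl peptide, in workflow order
_FORMS = ("hyl5", "hyl5_ox", "hyl5_ox_moa")


def _form_peptide(seq: str, mod_pos: int, form: str, protein: str, start: int,
                  charge: int) -> ModifiedPeptide:
    reg = builtin_registry()
    mods = [(i, "camC") for i, r in enumerate(seq, start=1) if r == "C"]
    mods.append((mod_pos, form))
    return ModifiedPeptide(
        seq, tuple(sorted(mods, key=lambda t: t[0])), charge=charge,
        protein=protein, start=start,
    )


def simulate_run(
    proteome: Mapping[str, str],
    truth: pd.DataFrame,
    config: SimConfig,
    run_id: str = "synthrun",
) -> tuple[list[SpectrumRecord], pd.DataFrame]:
    """Centroided MS1+MS2 run over the planted sites, plus scan-level truth.

    Each planted peptide elutes as a Gaussian MS1 peak per reaction form at
    the form's theoretical m/z with ppm jitter; MS2 spectra sample the
    conjugated form near the elution apex with fragment dropout and uniform
    noise peaks.
    """
    rng = np.random.default_rng(config.seed + 1)
    entries = []
    for row in truth.itertuples():
        seq = proteome[row.protein]
        blocked = sorted(
            truth.loc[truth.protein == row.protein, "position"].tolist()
        )
        span = _containing_peptide(seq, row.position, blocked)
        if span is None:
            continue
        start, end = span
        entries.append(
            {
                "protein": row.protein,
                "position": int(row.position),
                "start": start,
                "sequence": seq[start - 1 : end],
                "mod_pos": int(row.position) - start + 1,
            }
        )
    n = len(entries)
    run_length = 2 * config.rt_spacing_s + n * config.rt_spacing_s
    centers = config.rt_spacing_s + config.rt_spacing_s * np.arange(n)
    abundances = config.base_intensity * rng.lognormal(0.0, 0.5, size=n)

    spectra: list[SpectrumRecord] = []
    truth_scans = []
    scan_counter = 0
    times = np.arange(0.0, run_length, config.scan_interval_s)

    # precompute form m/z per entry
    form_mzs = np.empty((n, 3))
    for i, e in enumerate(entries):
        for f, form in enumerate(_FORMS):
            pep = _form_peptide(
                e["sequence"], e["mod_pos"], form, e["protein"], e["start"],
                config.charge,
            )
            form_mzs[i, f] = pep.mz()

    for t in times:
        mzs, its = [], []
        for i, e in enumerate(entries):
            g = math.exp(-0.5 * ((t - centers[i]) / config.peak_sigma_s) ** 2)
            if g < 1e-4:
                continue
            for f in range(3):
                inten = abundances[i] * config.form_fractions[f] * g
                if inten < 1.0:
                    continue
                jitter = rng.normal(0.0, config.ms1_jitter_ppm) * 1e-6
                mzs.append(form_mzs[i, f] * (1.0 + jitter))
                its.append(inten)
        for _ in range(config.ms1_noise_peaks):
            mzs.append(rng.uniform(375.0, 1600.0))
            its.append(rng.lognormal(6.0, 1.0))
        scan_counter += 1
        spectra.append(
            SpectrumRecord(
                run_id=run_id, scan_id=str(scan_counter), ms_level=1, rt=float(t),
                mz=np.array(mzs), intensity=np.array(its),
            )
        )

    search_params = SearchParams()
    for i, e in enumerate(entries):
        pep = _form_peptide(
            e["sequence"], e["mod_pos"], "hyl5_ox_moa", e["protein"], e["start"],
            config.charge,
        )
        ions = theoretical_spectrum(pep, search_params)
        frag = [ion for ion in ions if not ion.label.startswith("M(")]
        for k in range(config.ms2_per_peptide):
            rt = float(centers[i] + (k - config.ms2_per_peptide // 2) * 1.0)
            keep = rng.random(len(frag)) >= config.fragment_dropout
            mzs = [
                ion.mz * (1.0 + rng.normal(0.0, config.fragment_jitter_ppm) * 1e-6)
                for ion, kp in zip(frag, keep) if kp
            ]
            its = list(rng.lognormal(10.0, 1.0, size=len(mzs)))
            for _ in range(config.noise_peaks):
                mzs.append(rng.uniform(100.0, 1600.0))
                its.append(rng.lognormal(7.0, 1.0))
            jitter = rng.normal(0.0, config.ms1_jitter_ppm) * 1e-6
            scan_counter += 1
            spectra.append(
                SpectrumRecord(
                    run_id=run_id, scan_id=str(scan_counter), ms_level=2, rt=rt,
                    precursor_mz=form_mzs[i, 2] * (1.0 + jitter),
                    precursor_charge=config.charge,
                    mz=np.array(mzs), intensity=np.array(its),
                )
            )
            truth_scans.append(
                {
                    "run": run_id,
                    "scan_id": str(scan_counter),
                    "protein": e["protein"],
                    "position": e["position"],
                    "sequence": e["sequence"],
                    "form": "hyl5_ox_moa",
                }
            )
    spectra.sort(key=lambda s: (s.rt, int(s.scan_id)))
    return spectra, pd.DataFrame(
        truth_scans,
        columns=["run", "scan_id", "protein", "position", "sequence", "form"],
    )


def collagen_peptide(form: str = "hyl5", charge: int = 2) -> ModifiedPeptide:
    """The collagen benchmark peptide GFPGTPGLPGFKGIR with hydroxyproline at
    P3/P6/P9 and the 5-Hyl site at K12, in the requested reaction form."""
    if form not in _FORMS:
        raise ValueError(f"form must be one of {_FORMS}")
    pep = parse_peptide("GFP[hyp]GTP[hyp]GLP[hyp]GFK[hyl5]GIR", charge=charge)
    mods = tuple((p, form if n == "hyl5" else n) for p, n in pep.mods)
    return replace(pep, mods=mods, protein="COL1A2", start=164)


def simulate_collagen_run(
    config: SimConfig, run_id: str = "collagen"
) -> list[SpectrumRecord]:
    """MS1-only run of the collagen peptide's three reaction forms.

    The three forms co-elute as Gaussian peaks whose areas follow
    ``config.form_fractions``, at the theoretical 2+ m/z of each form —
    the fixture behind the XIC efficiency benchmark.
    """
    rng = np.random.default_rng(config.seed + 2)
    mzs3 = [collagen_peptide(f, config.charge).mz() for f in _FORMS]
    center = 5 * config.rt_spacing_s / 2
    run_length = 5 * config.rt_spacing_s
    spectra = []
    times = np.arange(0.0, run_length, config.scan_interval_s)
    for sc, t in enumerate(times, start=1):
        g = math.exp(-0.5 * ((t - center) / config.peak_sigma_s) ** 2)
        mzlist, itlist = [], []
        for f in range(3):
            inten = config.base_intensity * config.form_fractions[f] * g
            if inten < 1e-3:
                continue
            jitter = rng.normal(0.0, config.ms1_jitter_ppm) * 1e-6
            mzlist.append(mzs3[f] * (1.0 + jitter))
            itlist.append(inten)
        spectra.append(
            SpectrumRecord(
                run_id=run_id, scan_id=str(sc), ms_level=1, rt=float(t),
                mz=np.array(mzlist), intensity=np.array(itlist),
            )
        )
    return spectra


def simulate_quant(
    truth: pd.DataFrame, config: SimConfig
) -> tuple[SiteQuantMatrix, pd.DataFrame]:
    """Two-condition intensity matrix with planted effects and spike-ins.

    Site base abundances are log-normal; a seeded fraction of sites gains
    a log2 fold change drawn from N(log2_fc, log2_fc_sigma) in the treated
    condition; every sample
    is scaled by a log-normal spike-in factor that is also recorded as its
    spike-in area, so normalization can undo it exactly.
    """
    rng = np.random.default_rng(config.seed + 3)
    site_ids = [f"{r.protein}:{r.position}" for r in truth.itertuples()]
    n_sites = len(site_ids)
    n = config.n_per_group
    samples = [f"control_{i+1}" for i in range(n)] + [
        f"treated_{i+1}" for i in range(n)
    ]
    conditions = ["control"] * n + ["treated"] * n
    base = rng.normal(20.0, 1.5, size=n_sites)
    affected = rng.random(n_sites) < config.frac_affected
    drawn = rng.normal(config.log2_fc, config.log2_fc_sigma, size=n_sites)
    fcs = np.where(affected, drawn, 0.0)
    log2_vals = np.empty((n_sites, 2 * n))
    for j in range(2 * n):
        shift = fcs if j >= n else 0.0
        log2_vals[:, j] = base + shift + rng.normal(
            0.0, config.residual_sigma, size=n_sites
        )
    values = 2.0 ** log2_vals
    spike_factors = rng.lognormal(0.0, config.spikein_sigma, size=2 * n)
    values = values * spike_factors[None, :]
    frame = pd.DataFrame(values, index=site_ids, columns=samples)
    sheet = pd.DataFrame(
        {
            "condition": conditions,
            "replicate": list(range(1, n + 1)) * 2,
            "spikein_area": spike_factors * 1e6,
        },
        index=samples,
    )
    effects = pd.DataFrame(
        {"site": site_ids, "affected": affected, "log2_fc": fcs}
    ).set_index("site")
    return SiteQuantMatrix(values=frame, samples=sheet), effects
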