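"""Synthetic cohorts and histology fields with known ground truth.

The postmortem cohort behind this pipeline is not publicly distributable, so
every downstream stage is exercised on generated data that carries the same
statistical structure the analysis assumes:

* expression — negative-binomial counts per gene and sample, scaled to CPM
  by a simulated library size. The 19-gene stress panel gets latent-subgroup
  means taken from the reported schizophrenia subgroup contrasts (e.g. IL6
  0.77 vs 0.38 CPM, SOD2 84.7 vs 46.1 CPM); control subjects get the
  reported control-subgroup means where available and an attenuated version
  of the schizophrenia effect otherwise. Background genes share one mean
  across groups except for a planted gene set shifted by ``planted_log2fc``
  in the latent high-stress schizophrenia group.
* metadata — diagnosis, age, sex, RIN, PMI, antipsychotic dose,
  family-history flag and cause-of-death category with the broad covariate
  structure of a brain-bank cohort (lower RIN and more frequent family
  history outside the high-stress subgroup).
* histology — two-stain brightfield fields rendered as non-overlapping
  stained disks under a Beer–Lambert colour model, with per-field truth.

All randomness flows from the explicit per-spec seed; no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .histology import StainModel, default_stain_model
from .io import ExpressionMatrix, GeneSetCollection, SampleMetadata

def _around(base: float, ratio: float) -> tuple[float, float]:
    """Split a baseline mean into (high, low) with the given high/low ratio,
    keeping the geometric mean at the baseline."""
    s = float(np.sqrt(ratio))
    return (base * s, base / s)


#: High/low ratio assigned to panel genes whose subgroup contrast is a
#: reported trend rather than a reported pair of means: full-size effect
#: (comparable to the significant genes) paired with a large cv so that the
#: contrast stays sub-significant at n = 7/18.
_TREND_RATIO = 1.8
_TREND_CV = 0.45
#: Unreported direction-class genes co-move with the stress strata at half
#: the mean reported log-effect of their direction class (the reported up
#: genes average a ~2.0× ratio, the reported down genes ~0.62×).
_HALF_UP = np.sqrt(2.0)
_HALF_DOWN = np.sqrt(0.62)

#: Latent schizophrenia subgroup means (CPM) for the stress panel,
#: (mean_hsr, mean_lsr). The seven genes with reported subgroup contrasts
#: carry those means; the three genes reported as trending high in the
#: high-stress stratum get the trend ratio; the remaining direction-class
#: genes co-move at half effect; APOA2 and S100B are neutral. Baselines for
#: unreported genes are magnitudes typical for cortex bulk RNA-seq.
DEFAULT_PANEL_EFFECTS: dict[str, tuple[float, float]] = {
    "IL6": (0.77, 0.38),
    "IFNG": (0.14, 0.06),
    "SOD2": (84.7, 46.1),
    "DLG4": (14.5, 21.5),
    "SYP": (350.1, 556.3),
    "SNCA": (6.74, 11.26),
    "BDNF": (0.30, 0.51),
    "NR3C1": _around(42.0, _TREND_RATIO),
    "APOA1": _around(1.1, _TREND_RATIO),
    "SLC6A4": _around(0.5, _TREND_RATIO),
    "IL1B": _around(0.6, _HALF_UP**2),
    "TNF": _around(2.1, _HALF_UP**2),
    "SOD1": _around(210.0, _HALF_UP**2),
    "SOD3": _around(5.38, _HALF_UP**2),
    "IL10": _around(0.25, _HALF_DOWN**2),
    "SNCB": _around(88.0, _HALF_DOWN**2),
    "SNCG": _around(21.0, _HALF_DOWN**2),
    "APOA2": (0.35, 0.35),
    "S100B": (160.0, 160.0),
}

#: Within-group standard deviations (CPM) for the schizophrenia strata,
#: (sd_hsr, sd_lsr): the reported group SEMs scaled by √n (n = 7 and 18);
#: trend genes use the trend cv. Genes absent here fall back to the
#: cohort-wide NB dispersion.
DEFAULT_PANEL_SIGMAS: dict[str, tuple[float, float]] = {
    "IL6": (0.2646, 0.1697),
    "IFNG": (0.0529, 0.0424),
    "SOD2": (19.10, 9.84),
    "DLG4": (2.646, 4.455),
    "SYP": (147.05, 165.29),
    "SNCA": (1.958, 2.715),
    "BDNF": (0.1587, 0.2546),
    "NR3C1": tuple(_TREND_CV * m for m in _around(42.0, _TREND_RATIO)),
    "APOA1": tuple(_TREND_CV * m for m in _around(1.1, _TREND_RATIO)),
    "SLC6A4": tuple(_TREND_CV * m for m in _around(0.5, _TREND_RATIO)),
}

#: Control subgroup means (CPM) where the source cohort reports them
#: explicitly; other genes fall back to an attenuated schizophrenia effect.
DEFAULT_CONTROL_EFFECTS: dict[str, tuple[float, float]] = {
    "IL6": (0.59, 0.33),
    "SOD2": (79.6, 50.6),
    "SOD3": (6.95, 3.81),
    "DLG4": (15.2, 20.6),
    "SYP": (366.3, 558.5),
    "SNCA": (7.68, 12.12),
}

#: Control within-group sds from the reported control SEMs (n = 14 and 7).
DEFAULT_CONTROL_SIGMAS: dict[str, tuple[float, float]] = {
    "IL6": (0.262, 0.265),
    "SOD2": (38.05, 13.12),
    "SOD3": (2.47, 1.667),
    "DLG4": (4.34, 4.60),
    "SYP": (162.39, 91.02),
    "SNCA": (3.031, 1.958),
}

#: Canonical homologous-recombination DSB-repair genes used to name the
#: planted set when it has up to seven members.
DSB_HR_GENES = ["MRE11", "BRCA2", "ATRX", "RPA1", "POLA1", "LIG1", "GEN1"]

LATENT_GROUPS = ("SZ_HSR", "SZ_LSR", "CONT_HSR", "CONT_LSR")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study conditions: 25 schizophrenia cases split
    7 / 18 into latent high/low stress responders and 21 controls split
    14 / 7.
    """

    n_hsr: int = 7
    n_lsr: int = 18
    n_control_high: int = 14
    n_control_low: int = 7
    n_background_genes: int = 1000
    panel_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_EFFECTS)
    )
    panel_sigmas: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_SIGMAS)
    )
    control_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_EFFECTS)
    )
    control_sigmas: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_SIGMAS)
    )
    control_attenuation: float = 0.85
    nb_dispersion: float = 0.1
    planted_set_name: str = "DSB_REPAIR_HR"
    planted_set_size: int = 7
    planted_log2fc: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_hsr", "n_lsr", "n_control_high", "n_control_low",
                     "n_background_genes", "planted_set_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if any(m < 0 for pair in self.panel_effects.values() for m in pair):
            raise ValueError("panel means must be >= 0")
        if self.planted_set_size > self.n_background_genes:
            raise ValueError("planted set larger than background gene pool")

    @property
    def n_control(self) -> int:
        return self.n_control_high + self.n_control_low

    def planted_genes(self) -> list[str]:
        names = list(DSB_HR_GENES[: self.planted_set_size])
        for i in range(len(names), self.planted_set_size):
            names.append(f"HRX{i + 1}")
        return names


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = m + dispersion·m² (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size, p[pos])
    return out


def _nb_counts_per_entry(
    rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray
) -> np.ndarray:
    """NB draws with per-entry dispersion (Poisson where dispersion ≈ 0)."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.asarray(dispersion, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pois = (alpha <= 1e-12) & (mean > 0)
    nb = (alpha > 1e-12) & (mean > 0)
    out[pois] = rng.poisson(mean[pois])
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mean[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def generate_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, SampleMetadata, dict[str, str]]:
    """Simulate an expression matrix, metadata table and latent truth labels.

    Returns CPM values for the 19 stress-panel genes plus
    ``spec.n_background_genes`` background genes (the first
    ``planted_set_size`` of which are the planted set, named after the
    homologous-recombination repair pathway), a metadata table, and a map
    sample → latent group in ``LATENT_GROUPS``.
    """
    rng = np.random.default_rng(spec.rng_seed)

    sz_ids = [f"SZ{i + 1:02d}" for i in range(spec.n_hsr + spec.n_lsr)]
    ct_ids = [f"CT{i + 1:02d}" for i in range(spec.n_control)]
    samples = sz_ids + ct_ids
    latent = (
        ["SZ_HSR"] * spec.n_hsr
        + ["SZ_LSR"] * spec.n_lsr
        + ["CONT_HSR"] * spec.n_control_high
        + ["CONT_LSR"] * spec.n_control_low
    )
    truth = dict(zip(samples, latent))
    n_samples = len(samples)
    if n_samples == 0:
        raise ValueError("cohort has no samples")

    panel_genes = list(spec.panel_effects)
    planted = spec.planted_genes()
    background = planted + [
        f"BG{i + 1:04d}" for i in range(spec.n_background_genes - len(planted))
    ]
    genes = panel_genes + background

    # per-gene per-sample target CPM mean and (where specified) sd
    mean_cpm = np.empty((len(genes), n_samples), dtype=float)
    sd_cpm = np.full((len(genes), n_samples), np.nan)
    for gi, g in enumerate(panel_genes):
        hsr, lsr = spec.panel_effects[g]
        if g in spec.control_effects:
            c_hi, c_lo = spec.control_effects[g]
        else:
            mid = 0.5 * (hsr + lsr)
            c_hi = mid + spec.control_attenuation * (hsr - mid)
            c_lo = mid + spec.control_attenuation * (lsr - mid)
        per_group = {"SZ_HSR": hsr, "SZ_LSR": lsr, "CONT_HSR": c_hi, "CONT_LSR": c_lo}
        sig = {}
        if g in spec.panel_sigmas:
            sig["SZ_HSR"], sig["SZ_LSR"] = spec.panel_sigmas[g]
        if g in spec.control_sigmas:
            sig["CONT_HSR"], sig["CONT_LSR"] = spec.control_sigmas[g]
        elif g in spec.panel_sigmas:  # reuse the case-stratum spreads
            sig["CONT_HSR"], sig["CONT_LSR"] = spec.panel_sigmas[g]
        for s in range(n_samples):
            mean_cpm[gi, s] = per_group[latent[s]]
            if latent[s] in sig:
                sd_cpm[gi, s] = sig[latent[s]]

    # background gene baselines: log-normal across genes, median ~10 CPM;
    # planted genes use a mid-abundance window so the shift is detectable at
    # realistic counting depth.
    base = rng.lognormal(mean=np.log(10.0), sigma=1.5, size=len(background))
    base[: len(planted)] = rng.uniform(10.0, 100.0, size=len(planted))
    bg_block = np.tile(base[:, None], (1, n_samples))
    shift = 2.0**spec.planted_log2fc
    hsr_cols = [s for s in range(n_samples) if latent[s] == "SZ_HSR"]
    for gi in range(len(planted)):
        bg_block[gi, hsr_cols] *= shift
    mean_cpm[len(panel_genes):] = bg_block

    lib_sizes = rng.uniform(3.0e7, 5.0e7, size=n_samples)
    mean_counts = mean_cpm * lib_sizes[None, :] / 1.0e6
    # per-entry dispersion: genes with a target sd get the NB dispersion
    # that reproduces it on the CPM scale (floored at Poisson), the rest
    # share the cohort-wide dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = (sd_cpm / mean_cpm) ** 2
        alpha = cv2 - 1.0 / mean_counts
    alpha = np.where(np.isnan(sd_cpm), spec.nb_dispersion, np.maximum(alpha, 0.0))
    counts = _nb_counts_per_entry(rng, mean_counts, alpha)
    cpm = counts / lib_sizes[None, :] * 1.0e6

    matrix = ExpressionMatrix(pd.DataFrame(cpm, index=genes, columns=samples))
    meta = _generate_metadata(rng, samples, latent)
    return matrix, meta, truth


def _generate_metadata(
    rng: np.random.Generator, samples: list[str], latent: list[str]
) -> SampleMetadata:
    rows = []
    for s, grp in zip(samples, latent):
        is_sz = grp.startswith("SZ")
        if grp == "SZ_HSR":
            age, rin = rng.normal(74.3, 6.3), rng.normal(6.6, 0.7)
            fh_p, death_p = 0.03, (0.57, 0.29, 0.14)
        elif grp == "SZ_LSR":
            age, rin = rng.normal(66.1, 12.1), rng.normal(7.75, 0.9)
            fh_p, death_p = 0.45, (0.39, 0.44, 0.17)
        else:
            age, rin = rng.normal(66.4, 17.7), rng.normal(5.8, 1.2)
            fh_p, death_p = 0.05, (0.35, 0.5, 0.15)
        fh = "unknown"
        if rng.random() < 0.4:  # information available for a minority of cases
            fh = "present" if rng.random() < fh_p else "absent"
        rows.append(
            {
                "sample": s,
                "diagnosis": "SZ" if is_sz else "CONTROL",
                "age_years": round(float(np.clip(age, 30, 95)), 1),
                "sex": "M" if rng.random() < 0.62 else "F",
                "rin": round(float(np.clip(rin, 2.0, 10.0)), 2),
                "pmi_hours": round(float(rng.lognormal(np.log(12.0), 0.7)), 2),
                "cpz_eq_mg": round(float(max(rng.normal(559.0, 400.0), 0.0)), 1)
                if is_sz
                else np.nan,
                "family_history": fh,
                "death_category": ["inflammatory", "non_inflammatory", "malignancy"][
                    rng.choice(3, p=death_p)
                ],
            }
        )
    df = pd.DataFrame(rows).set_index("sample")
    return SampleMetadata(df)


def generate_gene_sets(
    spec: CohortSpec, n_decoy_sets: int = 30, decoy_size: int = 7
) -> GeneSetCollection:
    """Planted gene set plus decoy sets sampled from unshifted background genes.

    Decoys are disjoint from the planted set by construction; drawing is
    seeded from ``spec.rng_seed`` (offset so it does not reuse the cohort
    stream).
    """
    planted = spec.planted_genes()
    pool = [
        f"BG{i + 1:04d}"
        for i in range(spec.n_background_genes - len(planted))
    ]
    if decoy_size > len(pool):
        raise ValueError("decoy_size exceeds background gene pool")
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 7919]))
    sets: list[tuple[str, list[str]]] = [(spec.planted_set_name, planted)]
    for i in range(n_decoy_sets):
        members = rng.choice(pool, size=decoy_size, replace=False)
        sets.append((f"DECOY_{i + 1:03d}", list(members)))
    return GeneSetCollection(sets)


# --------------------------------------------------------------------------
# histology fields


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one rendered two-stain brightfield field.

    Cells are filled disks placed without overlap by rejection sampling;
    the stain amplitudes are optical densities along each stain vector and
    Gaussian read noise (sd in 8-bit intensity units) is added per channel.
    """

    width_px: int = 640
    height_px: int = 640
    n_tunel_pos: int = 5
    n_counterstained: int = 15
    cell_radius_px: tuple[int, int] = (28, 34)
    dab_od_amplitude: float = 1.0
    mg_od_amplitude: float = 0.8
    background_noise_sd: float = 2.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.cell_radius_px[0] < 1 or self.cell_radius_px[1] < self.cell_radius_px[0]:
            raise ValueError("cell radii must satisfy 1 <= min <= max")
        if self.n_tunel_pos < 0 or self.n_counterstained < 0:
            raise ValueError("cell counts must be >= 0")


@dataclass
class FieldTruth:
    n_tunel_pos: int
    n_counterstained: int
    centers: np.ndarray  # (N, 2) row/col
    radii: np.ndarray  # (N,)
    stain_index: np.ndarray  # (N,) 0 = TUNEL/DAB, 1 = counterstain


def render_field(
    spec: FieldSpec, stains: StainModel | None = None
) -> tuple[np.ndarray, FieldTruth]:
    """Render one field; returns the 8-bit RGB image and its ground truth.

    Transmitted intensity per channel is I_c = 255·10^(−OD_c) with
    OD_c = amplitude·stain_vector_c (Beer–Lambert composition), then noise
    and clipping to [0, 255].
    """
    stains = stains or default_stain_model()
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.height_px, spec.width_px
    n_total = spec.n_tunel_pos + spec.n_counterstained

    rmin, rmax = spec.cell_radius_px
    centers = np.zeros((n_total, 2), dtype=float)
    radii = np.zeros(n_total, dtype=int)
    placed = 0
    attempts = 0
    max_attempts = 2000 * max(n_total, 1)
    while placed < n_total:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_total} non-overlapping cells in "
                f"{w}x{h} after {max_attempts} attempts"
            )
        attempts += 1
        r = int(rng.integers(rmin, rmax + 1))
        cy = rng.uniform(r + 2, h - r - 2)
        cx = rng.uniform(r + 2, w - r - 2)
        d = np.hypot(centers[:placed, 0] - cy, centers[:placed, 1] - cx)
        if placed and (d < radii[:placed] + r + 2).any():
            continue
        centers[placed] = (cy, cx)
        radii[placed] = r
        placed += 1

    stain_index = np.array([0] * spec.n_tunel_pos + [1] * spec.n_counterstained)
    amplitudes = np.where(stain_index == 0, spec.dab_od_amplitude, spec.mg_od_amplitude)

    od = np.zeros((h, w, 3), dtype=float)
    basis = np.asarray(stains.vectors, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for i in range(n_total):
        cy, cx = centers[i]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radii[i] ** 2
        od[disk] += amplitudes[i] * basis[stain_index[i]]

    intensity = 255.0 * 10.0 ** (-od)
    if spec.background_noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.background_noise_sd, intensity.shape)
    image = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    truth = FieldTruth(
        n_tunel_pos=spec.n_tunel_pos,
        n_counterstained=spec.n_counterstained,
        centers=centers,
        radii=radii,
        stain_index=stain_index,
    )
    return image, truth


def render_case_fields(
    compositions: list[tuple[int, int]],
    base_spec: FieldSpec | None = None,
    stains: StainModel | None = None,
    rng_seed: int = 0,
) -> tuple[list[np.ndarray], list[FieldTruth]]:
    """Render one field per (n_tunel_pos, n_counterstained) composition."""
    base_spec = base_spec or FieldSpec()
    images, truths = [], []
    seeds = np.random.SeedSequence(rng_seed).generate_state(len(compositions))
    for (n_pos, n_neg), seed in zip(compositions, seeds):
        spec = replace(
            base_spec,
            n_tunel_pos=int(n_pos),
            n_counterstained=int(n_neg),
            rng_seed=int(seed % (2**31 - 1)),
        )
        img, tr = render_field(spec, stains)
        images.append(img)
        truths.append(tr)
    return images, truths
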