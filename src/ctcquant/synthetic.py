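"""Ground-truthed synthetic data for the CTC assay pipeline.

No public per-sample CTC data exist for this assay, so every analysis
stage is exercised against simulated inputs with known truth:

* :func:`generate_field` renders a multichannel fluorescence field of
  disk-shaped cells with per-phenotype intensity laws, a linear
  background plane and Gaussian noise, returning the image stack and a
  per-cell ground-truth table.
* :func:`generate_cell_table` is the tabular shortcut that skips the
  imaging stage and emits measured-style per-cell intensities directly.
* :func:`generate_cohort` draws a cohort of progressing/responding
  samples whose CTC densities follow group-level log-normal laws
  anchored to the reported clinical scale (progressing mean 19.8
  CTCs/mL, responding 2.3 CTCs/mL).
* :func:`generate_longitudinal` draws a serial-timepoint series for one
  patient.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.morphology import dilation as sk_dilation
from skimage.morphology import disk as sk_disk

from .core import (
    BIOMARKER,
    CAXII,
    CHANNEL_ROLES,
    CK,
    CTC_LABELS,
    EXCLUSION,
    LABEL_CAXII_S,
    LABEL_CK_S,
    LABEL_DP,
    LABEL_TRIPLE_NEG,
    LABEL_WBC,
    NUCLEAR,
    TRUTH_PREFIX,
    ChannelStack,
    bgsub_col,
)

__all__ = [
    "ChannelLaw",
    "BiomarkerMixture",
    "PhenotypeSpec",
    "CohortSpec",
    "default_phenotypes",
    "generate_field",
    "generate_cell_table",
    "generate_cohort",
    "generate_longitudinal",
]


@dataclass(frozen=True)
class ChannelLaw:
    """Intensity law for one channel of one phenotype.

    ``mean`` and ``sd`` are the arithmetic mean and standard deviation of
    the signal (fluorescence units above background).  ``dist`` selects a
    log-normal (default; fluorescence signal is non-negative and
    right-skewed) or normal draw.  A mean of zero denotes a channel with
    no specific signal.
    """

    mean: float
    sd: float = 0.0
    dist: str = "lognormal"

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError(f"intensity mean must be >= 0, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"intensity sd must be >= 0, got {self.sd}")
        if self.dist not in ("lognormal", "normal"):
            raise ValueError(f"unknown distribution {self.dist!r}")

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        if self.mean == 0 or self.sd == 0:
            return np.full(size if size is not None else (), float(self.mean))
        if self.dist == "normal":
            return rng.normal(self.mean, self.sd, size=size)
        # log-normal parameterised by its arithmetic moments
        sigma2 = math.log1p((self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class BiomarkerMixture:
    """Two-component mixture for the PD-L1/HLA-I channel of a phenotype.

    A fraction ``positive_fraction`` of cells carries the positive
    component ``N(pos_mean, pos_sd)``; the rest the negative component
    ``N(neg_mean, neg_sd)``.  Values live on the background-subtracted
    intensity scale, so the negative component is centred near zero and
    draws may be negative.  ``pos_mean - neg_mean`` is the component
    separation that cutoff-recovery tests sweep.
    """

    positive_fraction: float
    neg_mean: float = 0.0
    neg_sd: float = 30.0
    pos_mean: float = 300.0
    pos_sd: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError(
                f"positive_fraction must be in [0, 1], got {self.positive_fraction}"
            )

    def sample(self, rng: np.random.Generator, size: int):
        """Draw ``size`` values; returns ``(values, is_positive)``."""
        pos = rng.random(size) < self.positive_fraction
        vals = np.where(
            pos,
            rng.normal(self.pos_mean, self.pos_sd, size),
            rng.normal(self.neg_mean, self.neg_sd, size),
        )
        return vals, pos


@dataclass(frozen=True)
class PhenotypeSpec:
    """Ground-truth description of one cell phenotype."""

    label: str
    channels: dict[str, ChannelLaw] = field(default_factory=dict)
    biomarker: BiomarkerMixture = BiomarkerMixture(0.0)

    def law(self, role: str) -> ChannelLaw:
        return self.channels.get(role, ChannelLaw(0.0))


# Default intensity scale: nuclear stain bright and uniform across cells,
# marker signal ~500 units above a ~100-unit background.  The per-subtype
# biomarker positive-fractions follow the reported representative sample
# (CK single-positive 84%, double-positive 50%, CAXII single-positive 33%).
_NUCLEAR_LAW = ChannelLaw(600.0, 60.0)
_SIGNAL_LAW = ChannelLaw(500.0, 150.0)
_EXCLUSION_LAW = ChannelLaw(600.0, 180.0)
_NEGATIVE = ChannelLaw(0.0)

DEFAULT_BIOMARKER_FRACTIONS = {
    LABEL_CAXII_S: 0.33,
    LABEL_DP: 0.50,
    LABEL_CK_S: 0.84,
    LABEL_WBC: 0.0,
    LABEL_TRIPLE_NEG: 0.0,
}


def default_phenotypes(
    signal_law: ChannelLaw = _SIGNAL_LAW,
    exclusion_law: ChannelLaw = _EXCLUSION_LAW,
    biomarker_fractions: dict[str, float] | None = None,
) -> dict[str, PhenotypeSpec]:
    """Build the five stock phenotypes used throughout tests and demos."""
    fracs = dict(DEFAULT_BIOMARKER_FRACTIONS)
    if biomarker_fractions:
        fracs.update(biomarker_fractions)
    positive = {
        LABEL_CAXII_S: {CAXII: signal_law},
        LABEL_DP: {CAXII: signal_law, CK: signal_law},
        LABEL_CK_S: {CK: signal_law},
        LABEL_WBC: {EXCLUSION: exclusion_law},
        LABEL_TRIPLE_NEG: {},
    }
    out = {}
    for label, chans in positive.items():
        channels = {NUCLEAR: _NUCLEAR_LAW, CAXII: _NEGATIVE, CK: _NEGATIVE,
                    EXCLUSION: _NEGATIVE}
        channels.update(chans)
        out[label] = PhenotypeSpec(
            label=label,
            channels=channels,
            biomarker=BiomarkerMixture(fracs[label]),
        )
    return out


def _disk_offsets(radius: float):
    r = int(math.ceil(radius))
    rr, cc = np.mgrid[-r : r + 1, -r : r + 1]
    return rr, cc, (rr**2 + cc**2) <= radius**2


def _place_cells(
    rng: np.random.Generator,
    counts: list[int],
    field_shape: tuple[int, int],
    radius_range: tuple[float, float],
    clearance: float,
    min_separation: float | None,
    max_tries: int,
):
    """Draw non-clipping centres and radii; enforce separation if asked."""
    nrow, ncol = field_shape
    placed: list[tuple[float, float, float]] = []
    n_total = int(sum(counts))
    for _ in range(n_total):
        radius = rng.uniform(*radius_range)
        margin = radius + clearance + 4.0  # keep smoothed edge inside the field
        if 2 * margin >= min(nrow, ncol):
            raise ValueError(
                f"field {field_shape} too small for cells of radius {radius:.1f}"
            )
        for _try in range(max_tries):
            r0 = rng.uniform(margin, nrow - margin)
            c0 = rng.uniform(margin, ncol - margin)
            if min_separation is None:
                break
            ok = all(
                math.hypot(r0 - rp, c0 - cp)
                >= radius + rad_p + 2 * clearance + min_separation
                for rp, cp, rad_p in placed
            )
            if ok:
                break
        else:
            density = n_total / (nrow * ncol)
            raise RuntimeError(
                f"could not place cell {len(placed) + 1}/{n_total} after "
                f"{max_tries} tries at density {density:.2e} cells/px^2; "
                "reduce the mix or enlarge the field"
            )
        placed.append((r0, c0, radius))
    return placed


def generate_field(
    phenotype_mix: list[tuple[PhenotypeSpec, int]],
    field_shape: tuple[int, int] = (1024, 1024),
    background: tuple[float, float] = (100.0, 0.0),
    noise_sd: float = 20.0,
    seed: int | None = None,
    *,
    radius_range: tuple[float, float] = (8.0, 12.0),
    ring_width: float = 4.0,
    cytoplasm_extent: float = 10.0,
    edge_sigma: float = 1.0,
    min_separation: float | None = 4.0,
    max_tries: int = 2000,
    n_saturated_artifacts: int = 0,
    saturation_value: float = 65535.0,
):
    """Render one multichannel field plus its ground truth.

    Cells are uniform-intensity disks smoothed with a Gaussian of
    ``edge_sigma``: the nuclear disk has the drawn radius while
    marker/biomarker disks extend ``cytoplasm_extent`` further (the
    membrane/cytoplasm compartment reaches beyond the ``ring_width``
    measurement ring, so marker means are insensitive to small
    segmentation-boundary errors).  Background is
    ``level + gradient * col/(ncol-1)``; i.i.d. Gaussian noise of
    ``noise_sd`` is added and the result clipped at zero.

    Returns
    -------
    (ChannelStack, pandas.DataFrame)
        The image stack and the truth table with one row per cell:
        ``cell_id, label, row, col, radius, biomarker_positive``,
        per-channel law draws ``law_<role>`` and per-channel noiseless
        rendered mean signal over the ideal measurement footprint
        ``sig_<role>``.
    """
    rng = np.random.default_rng(seed)
    nrow, ncol = field_shape
    counts = [int(n) for _, n in phenotype_mix]
    if any(n < 0 for n in counts):
        raise ValueError("phenotype counts must be >= 0")

    centres = _place_cells(
        rng,
        counts + [int(n_saturated_artifacts)],
        field_shape,
        radius_range,
        cytoplasm_extent,
        min_separation,
        max_tries,
    )

    # Per-cell channel draws.
    specs: list[PhenotypeSpec] = []
    for spec, n in phenotype_mix:
        specs.extend([spec] * int(n))
    n_cells = len(specs)

    signal = {role: np.zeros(field_shape) for role in CHANNEL_ROLES}
    truth_rows = []
    for cid, (spec, (r0, c0, radius)) in enumerate(zip(specs, centres)):
        draws = {role: float(spec.law(role).sample(rng)) for role in
                 (NUCLEAR, CAXII, CK, EXCLUSION)}
        bval, bpos = spec.biomarker.sample(rng, 1)
        draws[BIOMARKER] = float(bval[0])
        ri, ci = int(round(r0)), int(round(c0))
        for role in CHANNEL_ROLES:
            rad = radius if role == NUCLEAR else radius + cytoplasm_extent
            rr, cc, mask = _disk_offsets(rad)
            rows, cols = rr[mask] + ri, cc[mask] + ci
            signal[role][rows, cols] += max(draws[role], 0.0)
        truth_rows.append(
            {
                "cell_id": cid,
                "label": spec.label,
                "row": float(r0),
                "col": float(c0),
                "radius": float(radius),
                "biomarker_positive": bool(bpos[0]),
                **{f"law_{role}": draws[role] for role in CHANNEL_ROLES},
            }
        )

    # Optional saturated artifacts for QC-flag tests (bright blobs on all
    # channels, not listed in the truth table as cells).
    for r0, c0, radius in centres[n_cells:]:
        ri, ci = int(round(r0)), int(round(c0))
        rr, cc, mask = _disk_offsets(radius + cytoplasm_extent)
        rows, cols = rr[mask] + ri, cc[mask] + ci
        for role in CHANNEL_ROLES:
            signal[role][rows, cols] = saturation_value

    if edge_sigma > 0:
        signal = {role: gaussian_filter(img, edge_sigma) for role, img in signal.items()}

    # Noiseless rendered mean over each cell's ideal measurement footprint
    # (nuclear disk dilated by ring_width): the quantity the measurement
    # stage estimates.
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "cell_id", "label", "row", "col", "radius", "biomarker_positive",
            *[f"law_{role}" for role in CHANNEL_ROLES],
        ],
    )
    for role in CHANNEL_ROLES:
        truth[f"sig_{role}"] = np.nan
    ring_foot = sk_disk(int(round(ring_width)))
    for i, (r0, c0, radius) in enumerate(centres[:n_cells]):
        ri, ci = int(round(r0)), int(round(c0))
        rr, cc, mask = _disk_offsets(radius)
        foot = sk_dilation(np.pad(mask, ring_foot.shape[0] // 2), ring_foot)
        frr, fcc = np.nonzero(foot)
        off = foot.shape[0] // 2
        rows = frr - off + ri
        cols = fcc - off + ci
        for role in CHANNEL_ROLES:
            truth.loc[i, f"sig_{role}"] = float(signal[role][rows, cols].mean())

    level, gradient = background
    plane = level + gradient * (np.arange(ncol) / max(ncol - 1, 1))[None, :]
    stack = {}
    for role in CHANNEL_ROLES:
        img = signal[role] + plane
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, field_shape)
        stack[role] = np.clip(img, 0.0, None)
    return ChannelStack(stack), truth


def generate_cell_table(
    phenotype_mix: list[tuple[PhenotypeSpec, float]],
    n_cells: int,
    seed: int | None = None,
    *,
    measurement_sd: float = 20.0,
    area_range: tuple[float, float] = (200.0, 800.0),
) -> pd.DataFrame:
    """Draw a measured-style per-cell table directly from phenotype laws.

    Emits the schema the gating stage consumes (``bgsub_<role>`` columns
    plus QC flags) with additive measurement noise of ``measurement_sd``
    on the marker channels, so negative-channel values scatter around
    zero with a genuine negative tail.  Hidden ground truth travels in
    ``truth_label`` / ``truth_biomarker_positive`` columns for test use
    only.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_cells > 0 and not phenotype_mix:
        raise ValueError("phenotype_mix is empty but n_cells > 0")
    rng = np.random.default_rng(seed)

    columns = [
        "cell_id", "area_px",
        *[bgsub_col(role) for role in CHANNEL_ROLES],
        "qc_saturated", "qc_size", "qc_border",
        f"{TRUTH_PREFIX}label", f"{TRUTH_PREFIX}biomarker_positive",
    ]
    if n_cells == 0:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            columns,
            [int, float] + [float] * len(CHANNEL_ROLES) + [bool] * 3 + [object, bool],
        )})

    specs = [s for s, _ in phenotype_mix]
    weights = np.asarray([w for _, w in phenotype_mix], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("phenotype weights must be >= 0 and sum > 0")
    weights = weights / weights.sum()
    which = rng.choice(len(specs), size=n_cells, p=weights)

    rows = []
    for cid, k in enumerate(which):
        spec = specs[k]
        rec = {"cell_id": cid, "area_px": float(rng.uniform(*area_range))}
        for role in (NUCLEAR, CAXII, CK, EXCLUSION):
            val = float(spec.law(role).sample(rng))
            rec[bgsub_col(role)] = val + float(rng.normal(0.0, measurement_sd))
        bval, bpos = spec.biomarker.sample(rng, 1)
        rec[bgsub_col(BIOMARKER)] = float(bval[0])
        rec.update(qc_saturated=False, qc_size=False, qc_border=False)
        rec[f"{TRUTH_PREFIX}label"] = spec.label
        rec[f"{TRUTH_PREFIX}biomarker_positive"] = bool(bpos[0])
        rows.append(rec)
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic progressing/responding cohort.

    Group CTC densities (cells per mL of blood) follow log-normal laws
    whose arithmetic means default to the reported clinical scale:
    19.8 CTCs/mL near radiographic progression versus 2.3 CTCs/mL while
    responding.  ``density_log_sd`` is the sigma of log-density shared by
    both groups.  Per-sample counts are Poisson(density x volume);
    subtype identity is multinomial with ``mixing`` proportions; per-cell
    biomarker values follow ``biomarker_mixtures``.
    """

    n_progressing: int = 11
    n_responding: int = 9
    progressing_density: float = 19.8
    responding_density: float = 2.3
    density_log_sd: float = 1.2
    mixing: dict[str, float] = field(
        default_factory=lambda: {LABEL_CAXII_S: 0.5, LABEL_DP: 0.3, LABEL_CK_S: 0.2}
    )
    volume_ml: float = 1.0
    biomarker_mixtures: dict[str, BiomarkerMixture] = field(
        default_factory=lambda: {
            label: BiomarkerMixture(DEFAULT_BIOMARKER_FRACTIONS[label])
            for label in CTC_LABELS
        }
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_progressing < 0 or self.n_responding < 0:
            raise ValueError("group sizes must be >= 0")
        if self.progressing_density <= 0 or self.responding_density <= 0:
            raise ValueError("group density means must be > 0")
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be > 0")
        if set(self.mixing) - set(CTC_LABELS):
            raise ValueError(f"mixing keys must be among {CTC_LABELS}")
        total = sum(self.mixing.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(f"mixing proportions must sum to 1, got {total}")


def _lognormal_density(rng, mean: float, log_sd: float, size: int):
    mu = math.log(mean) - log_sd**2 / 2.0  # arithmetic mean == `mean`
    return rng.lognormal(mu, log_sd, size)


def generate_cohort(spec: CohortSpec):
    """Draw a cohort; returns ``(samples, cells)`` DataFrames.

    ``samples``: one row per sample — ``sample_id, group, volume_ml`` and
    per-subtype counts ``n_caxii_s, n_dp, n_ck_s``.  ``cells``: one row
    per CTC — ``sample_id, truth_label, bgsub_biomarker,
    truth_biomarker_positive``.
    """
    rng = np.random.default_rng(spec.seed)
    groups = ["progressing"] * spec.n_progressing + ["responding"] * spec.n_responding
    means = {"progressing": spec.progressing_density,
             "responding": spec.responding_density}
    labels = list(spec.mixing)
    probs = np.asarray([spec.mixing[l] for l in labels])

    sample_rows, cell_rows = [], []
    for i, group in enumerate(groups):
        density = float(_lognormal_density(rng, means[group], spec.density_log_sd, 1)[0])
        count = int(rng.poisson(density * spec.volume_ml))
        split = rng.multinomial(count, probs)
        sid = f"S{i:03d}"
        rec = {"sample_id": sid, "group": group, "volume_ml": spec.volume_ml}
        for label in CTC_LABELS:
            rec[f"n_{label.lower()}"] = 0
        for label, n in zip(labels, split):
            rec[f"n_{label.lower()}"] = int(n)
        sample_rows.append(rec)
        for label, n in zip(labels, split):
            if n == 0:
                continue
            mix = spec.biomarker_mixtures.get(label, BiomarkerMixture(0.0))
            vals, pos = mix.sample(rng, int(n))
            for v, p in zip(vals, pos):
                cell_rows.append(
                    {
                        "sample_id": sid,
                        f"{TRUTH_PREFIX}label": label,
                        bgsub_col(BIOMARKER): float(v),
                        f"{TRUTH_PREFIX}biomarker_positive": bool(p),
                    }
                )
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "group", "volume_ml",
                 *[f"n_{l.lower()}" for l in CTC_LABELS]],
    )
    cells = pd.DataFrame(
        cell_rows,
        columns=["sample_id", f"{TRUTH_PREFIX}label", bgsub_col(BIOMARKER),
                 f"{TRUTH_PREFIX}biomarker_positive"],
    )
    return samples, cells


def generate_longitudinal(
    series_spec: list[tuple[float, dict[str, float]]],
    volume_ml: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a serial-timepoint series for one patient.

    ``series_spec`` lists ``(week, {subtype_label: density per mL})`` with
    strictly increasing weeks.  Counts per timepoint are
    Poisson(density x volume), as in :func:`generate_cohort`.
    """
    if volume_ml <= 0:
        raise ValueError("volume_ml must be > 0")
    weeks = [w for w, _ in series_spec]
    if any(b <= a for a, b in zip(weeks, weeks[1:])):
        raise ValueError(f"weeks must be strictly increasing, got {weeks}")
    rng = np.random.default_rng(seed)
    rows = []
    for week, densities in series_spec:
        if set(densities) - set(CTC_LABELS):
            raise ValueError(f"density keys must be among {CTC_LABELS}")
        rec = {"week": float(week), "volume_ml": float(volume_ml)}
        for label in CTC_LABELS:
            dens = float(densities.get(label, 0.0))
            if dens < 0:
                raise ValueError("densities must be >= 0")
            rec[f"n_{label.lower()}"] = int(rng.poisson(dens * volume_ml))
        rows.append(rec)
    return pd.DataFrame(
        rows, columns=["week", "volume_ml", *[f"n_{l.lower()}" for l in CTC_LABELS]]
    )
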