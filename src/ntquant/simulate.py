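"""Synthetic two-channel microscopy and cohort simulation with known truth.

Cells are rendered as disks with concentric circular nuclei; the
transcription-factor channel is piecewise-constant (nuclear plateau =
ratio x cytosolic plateau) before optional Poisson shot noise and additive
Gaussian read noise. This is deliberately the simplest geometry that
exercises every measurement path: the assay only ever compares a nuclear
region against a cytosolic one.

Per-cell N/C ratios are drawn from a two-component truncated-normal
mixture: a resting (baseline) component with mode ~0.58 and a minority
translocated component with elevated ratios. Sample sizes default to
75-100 cells per sample, the regime the assay is designed for.

The cohort simulator layers group structure (healthy / active / remission)
on top, couples a log-scale expression covariate to the true translocated
fraction, and emits qPCR Ct tables consistent with perfect amplification
doubling, so that downstream scoring and statistics can be checked against
fully known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SampleImage

__all__ = [
    "ImageSimConfig",
    "GroupSpec",
    "ExpressionCoupling",
    "CohortSimConfig",
    "QpcrSimConfig",
    "CellPlacementError",
    "simulate_sample",
    "simulate_ratio_table",
    "simulate_cohort",
    "simulate_qpcr",
    "default_cohort_config",
    "GROUND_TRUTH_COLUMNS",
]

GROUND_TRUTH_COLUMNS = [
    "cell_id",
    "center_row_px",
    "center_col_px",
    "cell_radius_px",
    "nucleus_radius_px",
    "true_nt_label",
    "true_ratio",
]


class CellPlacementError(RuntimeError):
    """Raised when the requested number of cells cannot be placed."""


@dataclass
class ImageSimConfig:
    """Parameters of one simulated sample image.

    ``n_cells=None`` draws the count uniformly from 75-100, the per-sample
    cell-count regime of the assay. ``nt_fraction`` is the true fraction of
    translocated cells; the realized count is exactly
    ``round(nt_fraction * n_cells)`` unless ``binomial_nt`` is set, so tests
    can assert integer ground truth.

    The baseline ratio component defaults to mean 0.58, SD 0.07 — the modal
    N/C ratio reported for resting monocytes. The translocated component
    (mean 1.2) is a free parameter of the simulator: real data constrain
    only that translocated ratios sit well above 1.5x the mode.
    """

    image_height_px: int = 768
    image_width_px: int = 768
    n_cells: int | None = None
    cell_radius_px: tuple[float, float] = (12.0, 16.0)
    nucleus_radius_fraction: float = 0.55
    nt_fraction: float = 0.0
    baseline_ratio_mean: float = 0.58
    baseline_ratio_sd: float = 0.07
    nt_ratio_mean: float = 1.2
    nt_ratio_sd: float = 0.15
    cyto_intensity_mean: float = 2000.0
    nuclear_stain_intensity: float = 8000.0
    gaussian_noise_sd: float = 10.0
    poisson_noise: bool = False
    min_cell_gap_px: int = 8
    binomial_nt: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_cells is not None and self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        lo, hi = self.cell_radius_px
        if lo <= 0 or hi < lo:
            raise ValueError("cell_radius_px must be a positive (low, high) range")
        if not 0.0 < self.nucleus_radius_fraction < 1.0:
            raise ValueError("nucleus_radius_fraction must lie in (0, 1)")
        if not 0.0 <= self.nt_fraction <= 1.0:
            raise ValueError("nt_fraction must lie in [0, 1]")
        for name in (
            "baseline_ratio_mean",
            "baseline_ratio_sd",
            "nt_ratio_mean",
            "nt_ratio_sd",
            "cyto_intensity_mean",
            "nuclear_stain_intensity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gaussian_noise_sd < 0:
            raise ValueError("gaussian_noise_sd must be nonnegative")
        if self.min_cell_gap_px < 0:
            raise ValueError("min_cell_gap_px must be nonnegative")


def _draw_n_cells(config: ImageSimConfig, rng: np.random.Generator) -> int:
    if config.n_cells is not None:
        return config.n_cells
    return int(rng.integers(75, 101))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal draws truncated below at 0 by resampling (negligible mass there)."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def _draw_nt_labels(
    config: ImageSimConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    if config.binomial_nt:
        return rng.random(n) < config.nt_fraction
    n_nt = int(math.floor(config.nt_fraction * n + 0.5))
    labels = np.zeros(n, dtype=bool)
    labels[rng.permutation(n)[:n_nt]] = True
    return labels


def _draw_ratios(
    config: ImageSimConfig, labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = labels.size
    ratios = np.empty(n)
    n_nt = int(labels.sum())
    if n - n_nt:
        ratios[~labels] = _truncated_normal(
            rng, config.baseline_ratio_mean, config.baseline_ratio_sd, n - n_nt
        )
    if n_nt:
        ratios[labels] = _truncated_normal(
            rng, config.nt_ratio_mean, config.nt_ratio_sd, n_nt
        )
    return ratios


def _place_cells(
    config: ImageSimConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place non-overlapping disks by rejection sampling.

    Returns (center_rows, center_cols, radii). Raises CellPlacementError,
    naming the achieved count, if the image cannot fit ``n`` disks within a
    bounded number of attempts.
    """
    lo, hi = config.cell_radius_px
    gap = float(config.min_cell_gap_px)
    rows: list[float] = []
    cols: list[float] = []
    radii: list[float] = []
    max_attempts = 200 * n
    attempts = 0
    while len(rows) < n and attempts < max_attempts:
        attempts += 1
        r = rng.uniform(lo, hi)
        margin = r + 1.0
        if (
            config.image_height_px <= 2 * margin
            or config.image_width_px <= 2 * margin
        ):
            continue
        cy = rng.uniform(margin, config.image_height_px - margin)
        cx = rng.uniform(margin, config.image_width_px - margin)
        if rows:
            d2 = (np.asarray(rows) - cy) ** 2 + (np.asarray(cols) - cx) ** 2
            min_d = np.asarray(radii) + r + gap
            if np.any(d2 < min_d**2):
                continue
        rows.append(cy)
        cols.append(cx)
        radii.append(r)
    if len(rows) < n:
        raise CellPlacementError(
            f"could not place {n} non-overlapping cells "
            f"(achieved {len(rows)} after {max_attempts} attempts); "
            "enlarge the image or reduce n_cells/min_cell_gap_px"
        )
    return np.asarray(rows), np.asarray(cols), np.asarray(radii)


def _ground_truth_frame(
    rows: np.ndarray,
    cols: np.ndarray,
    radii: np.ndarray,
    nucleus_radii: np.ndarray,
    labels: np.ndarray,
    ratios: np.ndarray,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, rows.size + 1, dtype=int),
            "center_row_px": rows,
            "center_col_px": cols,
            "cell_radius_px": radii,
            "nucleus_radius_px": nucleus_radii,
            "true_nt_label": labels,
            "true_ratio": ratios,
        },
        columns=GROUND_TRUTH_COLUMNS,
    )


def simulate_sample(
    config: ImageSimConfig, sample_id: str = "sim"
) -> tuple[SampleImage, pd.DataFrame]:
    """Render one two-channel sample image plus its ground-truth table.

    Channel 1 shows nuclear disks at ``nuclear_stain_intensity``; channel 2
    shows whole-cell TF signal whose per-cell nuclear/cytosolic plateau
    ratio equals ``true_ratio`` before noise. Pixel coordinates are 0-based,
    row-major and pixel-centered: pixel (i, j) belongs to a disk when its
    center lies within the disk radius.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = _draw_n_cells(config, rng)
    labels = _draw_nt_labels(config, n, rng)
    ratios = _draw_ratios(config, labels, rng)
    rows, cols, radii = _place_cells(config, n, rng)
    nucleus_radii = radii * config.nucleus_radius_fraction

    shape = (config.image_height_px, config.image_width_px)
    nuclear = np.zeros(shape)
    tf = np.zeros(shape)
    for i in range(n):
        cy, cx, r, rn = rows[i], cols[i], radii[i], nucleus_radii[i]
        r0 = max(0, int(math.floor(cy - r)) - 1)
        r1 = min(shape[0], int(math.ceil(cy + r)) + 2)
        c0 = max(0, int(math.floor(cx - r)) - 1)
        c1 = min(shape[1], int(math.ceil(cx + r)) + 2)
        ii, jj = np.mgrid[r0:r1, c0:c1]
        d2 = (ii - cy) ** 2 + (jj - cx) ** 2
        cell = d2 <= r**2
        nuc = d2 <= rn**2
        nuclear[r0:r1, c0:c1][nuc] = config.nuclear_stain_intensity
        tf[r0:r1, c0:c1][cell & ~nuc] = config.cyto_intensity_mean
        tf[r0:r1, c0:c1][nuc] = ratios[i] * config.cyto_intensity_mean

    if config.poisson_noise:
        nuclear = rng.poisson(nuclear).astype(float)
        tf = rng.poisson(tf).astype(float)
    if config.gaussian_noise_sd > 0:
        nuclear = nuclear + rng.normal(0, config.gaussian_noise_sd, shape)
        tf = tf + rng.normal(0, config.gaussian_noise_sd, shape)
    nuclear = np.clip(nuclear, 0, None)
    tf = np.clip(tf, 0, None)

    image = SampleImage(nuclear_channel=nuclear, tf_channel=tf, sample_id=sample_id)
    truth = _ground_truth_frame(rows, cols, radii, nucleus_radii, labels, ratios)
    return image, truth


def simulate_ratio_table(
    config: ImageSimConfig, sample_id: str = "sim"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-cell ratios from the image simulator's mixture, skipping rendering.

    The fast path for statistics tests: the returned table holds the exact
    mixture draws (no imaging noise), one row per cell, alongside a
    geometry-free ground-truth table. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = _draw_n_cells(config, rng)
    labels = _draw_nt_labels(config, n, rng)
    ratios = _draw_ratios(config, labels, rng)
    cell_ids = np.arange(1, n + 1, dtype=int)
    table = pd.DataFrame(
        {"sample_id": sample_id, "cell_id": cell_ids, "nc_ratio": ratios}
    )
    truth = pd.DataFrame(
        {"cell_id": cell_ids, "true_nt_label": labels, "true_ratio": ratios}
    )
    return table, truth


# --------------------------------------------------------------------------
# cohort simulation


@dataclass
class GroupSpec:
    """One cohort group: its label, size, and per-sample parameter draws.

    ``nt_fraction_dist`` draws each sample's true translocated fraction;
    ``activity_dist`` draws a nonnegative-integer disease-activity score.
    Distributions are (kind, params) pairs so configs stay JSON-serializable:
    supported kinds are ``fixed`` (value), ``uniform`` (low, high),
    ``beta`` (a, b) for fractions, and ``fixed`` / ``randint`` (low, high,
    inclusive) / ``poisson`` (lam) for activity scores.
    """

    label: str
    n_samples: int
    nt_fraction_dist: tuple[str, dict]
    activity_dist: tuple[str, dict] = ("fixed", {"value": 0})

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


def _sample_fraction(dist: tuple[str, dict], rng: np.random.Generator) -> float:
    kind, p = dist
    if kind == "fixed":
        x = float(p["value"])
    elif kind == "uniform":
        lo, hi = float(p["low"]), float(p["high"])
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("uniform fraction bounds must satisfy 0 <= low <= high <= 1")
        x = float(rng.uniform(lo, hi))
    elif kind == "beta":
        x = float(rng.beta(float(p["a"]), float(p["b"])))
    else:
        raise ValueError(f"unknown fraction distribution kind: {kind!r}")
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"sampled nt_fraction {x} outside [0, 1]")
    return x


def _sample_activity(dist: tuple[str, dict], rng: np.random.Generator) -> int:
    kind, p = dist
    if kind == "fixed":
        x = int(p["value"])
    elif kind == "randint":
        x = int(rng.integers(int(p["low"]), int(p["high"]) + 1))
    elif kind == "poisson":
        x = int(rng.poisson(float(p["lam"])))
    else:
        raise ValueError(f"unknown activity distribution kind: {kind!r}")
    if x < 0:
        raise ValueError("activity score must be nonnegative")
    return x


@dataclass
class ExpressionCoupling:
    """Log-linear coupling of an expression covariate to NT prevalence.

    log(expression) = intercept + slope * prevalence_pct + N(0, noise_sd).
    The downstream analysis only uses rank correlation, so any monotone
    coupling is faithful; log-linear keeps expression strictly positive.
    """

    intercept: float = 0.0
    slope: float = 0.15
    noise_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class CohortSimConfig:
    """A cohort of samples with group structure and a coupled covariate.

    ``image_config`` supplies everything about the per-sample ratio mixture
    except ``nt_fraction`` and ``seed``, which are drawn per sample.
    """

    groups: list[GroupSpec]
    expression_coupling: ExpressionCoupling = field(default_factory=ExpressionCoupling)
    image_config: ImageSimConfig = field(default_factory=ImageSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")


def default_cohort_config(seed: int = 0) -> CohortSimConfig:
    """A cohort emulating the assay's human study structure.

    25 healthy donors with rare translocation (median true fraction ~1%),
    plus 18 active-phase and 26 remission-phase patients drawn from a
    common elevated distribution (quartiles roughly 3-10%), reflecting the
    observation that translocation prevalence stays elevated in remission.
    Activity scores mimic a disease-activity index with the active/remission
    boundary at 5.
    """
    groups = [
        GroupSpec(
            "healthy", 25, ("beta", {"a": 1.0, "b": 60.0}), ("randint", {"low": 0, "high": 2})
        ),
        GroupSpec(
            "active", 18, ("beta", {"a": 1.3, "b": 17.0}), ("randint", {"low": 5, "high": 20})
        ),
        GroupSpec(
            "remission", 26, ("beta", {"a": 1.3, "b": 17.0}), ("randint", {"low": 0, "high": 4})
        ),
    ]
    return CohortSimConfig(groups=groups, seed=seed)


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate per-sample ratio tables plus cohort metadata.

    Returns ``(ratio_tables, metadata, truths)`` where ``ratio_tables`` maps
    sample_id to a per-cell ratio table, ``metadata`` has one row per sample
    (sample_id, group, activity_score, expression, true_nt_fraction,
    n_cells), and ``truths`` maps sample_id to the per-cell ground truth.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    tables: dict[str, pd.DataFrame] = {}
    truths: dict[str, pd.DataFrame] = {}
    meta_rows = []
    base = config.image_config
    for group in config.groups:
        for k in range(group.n_samples):
            sample_id = f"{group.label}_{k + 1:03d}"
            frac = _sample_fraction(group.nt_fraction_dist, rng)
            activity = _sample_activity(group.activity_dist, rng)
            sample_seed = int(rng.integers(0, 2**31 - 1))
            cfg = ImageSimConfig(
                image_height_px=base.image_height_px,
                image_width_px=base.image_width_px,
                n_cells=base.n_cells,
                cell_radius_px=base.cell_radius_px,
                nucleus_radius_fraction=base.nucleus_radius_fraction,
                nt_fraction=frac,
                baseline_ratio_mean=base.baseline_ratio_mean,
                baseline_ratio_sd=base.baseline_ratio_sd,
                nt_ratio_mean=base.nt_ratio_mean,
                nt_ratio_sd=base.nt_ratio_sd,
                cyto_intensity_mean=base.cyto_intensity_mean,
                nuclear_stain_intensity=base.nuclear_stain_intensity,
                gaussian_noise_sd=base.gaussian_noise_sd,
                poisson_noise=base.poisson_noise,
                min_cell_gap_px=base.min_cell_gap_px,
                binomial_nt=base.binomial_nt,
                seed=sample_seed,
            )
            table, truth = simulate_ratio_table(cfg, sample_id=sample_id)
            tables[sample_id] = table
            truths[sample_id] = truth
            prev_pct = 100.0 * frac
            coup = config.expression_coupling
            log_expr = coup.intercept + coup.slope * prev_pct
            if coup.noise_sd > 0:
                log_expr += rng.normal(0, coup.noise_sd)
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "group": group.label,
                    "activity_score": activity,
                    "expression": float(np.exp(log_expr)),
                    "true_nt_fraction": frac,
                    "n_cells": len(table),
                }
            )
    metadata = pd.DataFrame(meta_rows)
    return tables, metadata, truths


# --------------------------------------------------------------------------
# qPCR simulation


@dataclass
class QpcrSimConfig:
    """Simulated qPCR Ct tables under perfect amplification doubling.

    ``true_fold_changes`` maps gene -> {group -> fold change relative to the
    calibrator group}; the reference gene must have fold change 1 in every
    group. Ct values follow Ct = reference_ct_mean - log2(expression) +
    noise, i.e. one cycle per factor of two (amplification efficiency fixed
    at 2).
    """

    genes: list[str]
    reference_gene: str
    true_fold_changes: dict[str, dict[str, float]]
    n_samples_per_group: dict[str, int]
    reference_ct_mean: float = 20.0
    ct_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_gene not in self.genes:
            raise ValueError("reference gene must be listed in genes")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be nonnegative")
        for gene in self.genes:
            if gene == self.reference_gene:
                continue
            if gene not in self.true_fold_changes:
                raise ValueError(f"missing fold changes for gene {gene!r}")
            for group, fc in self.true_fold_changes[gene].items():
                if fc <= 0:
                    raise ValueError(
                        f"fold change for {gene!r} in group {group!r} must be positive"
                    )
        ref_fc = self.true_fold_changes.get(self.reference_gene)
        if ref_fc is not None and any(fc != 1.0 for fc in ref_fc.values()):
            raise ValueError("reference gene fold change must be 1 in every group")


def simulate_qpcr(config: QpcrSimConfig) -> pd.DataFrame:
    """Simulate a long-format Ct table (sample_id, group, gene, ct).

    The reference gene amplifies at ``reference_ct_mean`` in every sample;
    a target with fold change F in its group comes up log2(F) cycles
    earlier. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for group, n in config.n_samples_per_group.items():
        for k in range(n):
            sample_id = f"{group}_{k + 1:03d}"
            for gene in config.genes:
                if gene == config.reference_gene:
                    expr = 1.0
                else:
                    try:
                        expr = config.true_fold_changes[gene][group]
                    except KeyError:
                        raise ValueError(
                            f"no fold change for gene {gene!r} in group {group!r}"
                        ) from None
                ct = config.reference_ct_mean - math.log2(expr)
                if config.ct_noise_sd > 0:
                    ct += rng.normal(0, config.ct_noise_sd)
                rows.append(
                    {"sample_id": sample_id, "group": group, "gene": gene, "ct": ct}
                )
    return pd.DataFrame(rows)
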