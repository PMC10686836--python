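"""Synthetic swarm data with the statistical structure the analysis assumes.

Generates every input of the pipeline: exponential boundary growth
observations, radial sampling grids, log2 expression fields that are
noisy linear combinations of the domain basis, overdispersed count
matrices with unequal library sizes, cell configurations (isotropic,
rafts, non-motile clusters), and secrete-then-consume metabolite
kinetics with a front-arrival time shift.

Defaults emulate the study conditions: a swarm expanding from 1 mm to
60 mm diameter in ~6 h (growth timescale tau = 6/ln(60) ≈ 1.47 h),
three replicates, up to 9 regularly spaced radial positions starting at
1.5 mm, and libraries of a few million reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .basis import BasisSet
from .domain import BoundaryObservations, SampleAnnotation
from .metabolites import MetaboliteSeries

#: tau such that the boundary grows 60-fold (1 mm -> 60 mm diameter) in 6 h
DEFAULT_TAU = 6.0 / math.log(60.0)


@dataclass
class SyntheticConfig:
    """Ground-truth generator parameters.

    tau : growth timescale (h); b0_per_replicate : initial radii (mm);
    t_end : experiment duration (h); noise_sd : Gaussian noise SD on the
    log2 expression field; nb_dispersion : negative-binomial dispersion
    of the count model; library_size_range : bounds on total counts per
    sample.
    """

    tau: float = DEFAULT_TAU
    b0_per_replicate: list[float] = field(default_factory=lambda: [0.5, 0.55, 0.6])
    t_end: float = 6.0
    n_genes: int = 600
    noise_sd: float = 0.2
    nb_dispersion: float = 0.05
    library_size_range: tuple[float, float] = (2e6, 5e6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if any(b <= 0 for b in self.b0_per_replicate):
            raise ValueError("b0 values must be positive")
        if self.noise_sd < 0 or self.nb_dispersion < 0:
            raise ValueError("noise_sd and nb_dispersion must be nonnegative")

    def to_yaml(self) -> str:
        d = dict(self.__dict__)
        d["library_size_range"] = list(self.library_size_range)
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticConfig":
        d = yaml.safe_load(text)
        d["library_size_range"] = tuple(d["library_size_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """True spectral coefficients and per-gene statistics.

    ``coefficients[n, m]`` is the true coefficient of basis function P_m
    for gene n, in the units of the log2 expression field; ``patterned``
    flags genes with nonzero higher-order coefficients.
    """

    coefficients: np.ndarray
    gene_means: np.ndarray
    gene_sds: np.ndarray
    patterned: np.ndarray
    family: np.ndarray | None = None    # pattern-family label, -1 for flat genes


def gen_boundary_observations(config: SyntheticConfig, obs_noise: float = 0.0,
                              interval_h: float = 0.25,
                              rng: np.random.Generator | None = None
                              ) -> list[BoundaryObservations]:
    """Boundary radius series b0 * exp(t/tau) + noise per replicate."""
    rng = rng or np.random.default_rng(config.seed)
    out = []
    times = np.arange(0.0, config.t_end + 1e-9, interval_h)
    for i, b0 in enumerate(config.b0_per_replicate):
        radii = b0 * np.exp(times / config.tau)
        if obs_noise > 0:
            radii = radii + rng.normal(0.0, obs_noise, radii.size)
        radii = np.maximum(radii, 1e-6)
        out.append(BoundaryObservations(f"rep{i + 1}", times, radii))
    return out


def radial_positions(boundary_radius: float, innermost: float = 1.5,
                     min_spacing: float = 1.0, max_positions: int = 9,
                     margin: float = 0.95) -> np.ndarray:
    """Regularly spaced radial sampling positions inside the boundary.

    Positions start at ``innermost`` with 1 mm spacing; once the boundary
    is large enough that more than ``max_positions`` would fit, the same
    count is spread evenly out to ``margin`` x boundary.
    """
    if boundary_radius < innermost:
        return np.empty(0)
    n_unit = int((boundary_radius - innermost) // min_spacing) + 1
    if n_unit <= max_positions:
        return innermost + min_spacing * np.arange(n_unit)
    outer = margin * boundary_radius
    return np.linspace(innermost, outer, max_positions)


def gen_sampling_grid(tau: float, b0_per_replicate: list[float], t_end: float,
                      interval_min: float = 20.0, max_positions: int = 9,
                      innermost: float = 1.5) -> list[SampleAnnotation]:
    """Space-time sampling annotations for all replicates.

    Samples are taken every ``interval_min`` minutes; at each time, up to
    ``max_positions`` regularly spaced radial positions (innermost at
    1.5 mm, spacing >= 1 mm) inside the current boundary.
    """
    if not 1.0 <= interval_min <= 60.0:
        raise ValueError("sampling interval must be reasonable (1-60 min)")
    out = []
    times = np.arange(0.0, t_end + 1e-9, interval_min / 60.0)
    for i, b0 in enumerate(b0_per_replicate):
        rep = f"rep{i + 1}"
        for t in times:
            b = b0 * math.exp(t / tau)
            for p in radial_positions(b, innermost=innermost,
                                      max_positions=max_positions):
                sid = f"{rep}_t{t:05.2f}_p{p:05.2f}"
                out.append(SampleAnnotation(sid, rep, float(t), float(p), float(b)))
    return out


def make_ground_truth(basis: BasisSet, n_genes: int, n_patterned: int,
                      rng: np.random.Generator,
                      mean_range: tuple[float, float] = (4.0, 10.0),
                      amplitude: float = 1.0) -> GroundTruth:
    """Random cohort: flat genes plus genes with higher-order structure."""
    if n_patterned > n_genes:
        raise ValueError("n_patterned exceeds n_genes")
    M1 = basis.size
    mu = rng.uniform(*mean_range, n_genes)
    coef = np.zeros((n_genes, M1))
    coef[:, 0] = mu / basis.p0           # constant part carries the mean
    patterned = np.zeros(n_genes, dtype=bool)
    patterned[:n_patterned] = True
    high = rng.normal(0.0, amplitude, (n_patterned, M1 - 1))
    # keep amplitudes bounded away from zero so flags stay meaningful
    norms = np.linalg.norm(high, axis=1, keepdims=True)
    high = high / norms * np.maximum(norms, 0.5 * amplitude)
    coef[:n_patterned, 1:] = high
    sds = np.linalg.norm(coef[:, 1:], axis=1)
    return GroundTruth(coefficients=coef, gene_means=mu, gene_sds=sds,
                       patterned=patterned)


def make_pattern_cohort(basis: BasisSet, n_flat: int, n_per_family: int,
                        rng: np.random.Generator,
                        amplitude: float = 2.0, jitter: float = 0.1,
                        mean_range: tuple[float, float] = (4.0, 10.0)
                        ) -> GroundTruth:
    """Cohort with six planted pattern families plus flat genes.

    Family templates are the axis directions ±e1, ±e2, ±e3 in the
    higher-coefficient space: zero cosine similarity between different
    axes and -1 between a family and its sign-flipped partner, so the
    families are maximally separated under cosine distance.  Members get
    small isotropic jitter around the template.
    """
    M1 = basis.size
    if M1 < 4:
        raise ValueError("need at least 4 basis functions for 6 families")
    templates = []
    for axis in range(3):
        for sign in (1.0, -1.0):
            t = np.zeros(M1 - 1)
            t[axis] = sign
            templates.append(t)
    n_families = len(templates)
    n_genes = n_flat + n_families * n_per_family
    mu = rng.uniform(*mean_range, n_genes)
    coef = np.zeros((n_genes, M1))
    coef[:, 0] = mu / basis.p0
    family = np.full(n_genes, -1)
    patterned = np.zeros(n_genes, dtype=bool)
    i = 0
    for f, tpl in enumerate(templates):
        for _ in range(n_per_family):
            v = amplitude * tpl + rng.normal(0.0, jitter * amplitude, M1 - 1)
            coef[i, 1:] = v
            family[i] = f
            patterned[i] = True
            i += 1
    sds = np.linalg.norm(coef[:, 1:], axis=1)
    return GroundTruth(coefficients=coef, gene_means=mu, gene_sds=sds,
                       patterned=patterned, family=family)


def gen_expression_field(truth: GroundTruth, design: np.ndarray,
                         noise_sd: float,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """log2 expression matrix (genes x samples) from true coefficients.

    With ``noise_sd = 0`` every row is an exact linear combination of the
    basis evaluated at the sample coordinates, so the spectral fit
    recovers the coefficients to numerical precision.
    """
    if truth.coefficients.shape[1] != design.shape[1]:
        raise ValueError("truth and design basis dimensions disagree")
    values = truth.coefficients @ design.T
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        values = values + rng.normal(0.0, noise_sd, values.shape)
    return values


def gen_count_matrix(log2_expression: np.ndarray, library_sizes: np.ndarray,
                     nb_dispersion: float, seed: int) -> np.ndarray:
    """Overdispersed counts with the given expected library sizes.

    Per-sample expected counts are the linear-scale expression
    2^(log2 values) renormalized to the library size; counts are drawn
    negative-binomially via the gamma-Poisson mixture with dispersion
    phi (variance m + phi m²).  ``phi = 0`` reduces to Poisson, a zero
    library size to an all-zero column.
    """
    expr = np.asarray(log2_expression, float)
    if not np.all(np.isfinite(expr)):
        raise ValueError("non-finite expression values")
    lib = np.asarray(library_sizes, float)
    if np.any(lib < 0):
        raise ValueError("negative library size")
    rng = np.random.default_rng(seed)
    linear = 2.0 ** expr
    colsum = linear.sum(axis=0)
    means = linear / colsum[None, :] * lib[None, :]
    if nb_dispersion > 0:
        shape = 1.0 / nb_dispersion
        lam = rng.gamma(shape, means * nb_dispersion)
    else:
        lam = means
    return rng.poisson(lam)


_SCENARIOS = ("isotropic", "raft", "non_motile_cluster", "mixed")


def gen_cell_table(scenario: str, n_cells: int, field_size: float,
                   seed: int, n_frames: int = 1) -> pd.DataFrame:
    """Cell configurations for the phenotype metrics.

    ``isotropic``: uniform positions and axial orientations, motile
    speeds.  ``raft``: a tight co-moving group (common orientation within
    ±2°, speed >= 15 µm/s) isolated from an isotropic background by more
    than the 30 µm neighbourhood radius.  ``non_motile_cluster``: a chain
    of >= 10 near-stationary cells at 1.5 µm spacing in a motile
    background.  ``mixed``: raft + cluster + background.

    Returns a frame-indexed table (columns frame, x, y, orientation,
    speed, area) suitable for ``phenotypes.CellTable``.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {_SCENARIOS}")
    if n_cells < 0:
        raise ValueError("n_cells must be nonnegative")
    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n_frames):
        parts = []
        remaining = n_cells
        if scenario in ("raft", "mixed") and n_cells > 0:
            n_raft = max(min(20, n_cells), n_cells // 4)
            n_raft = min(n_raft, n_cells)
            center = np.array([field_size * 0.25, field_size * 0.25])
            ang = rng.uniform(0, np.pi)
            parts.append(pd.DataFrame({
                "x": center[0] + rng.uniform(-10, 10, n_raft),
                "y": center[1] + rng.uniform(-10, 10, n_raft),
                "orientation": (ang + rng.uniform(-np.deg2rad(2), np.deg2rad(2),
                                                  n_raft)) % np.pi,
                "speed": rng.uniform(15, 25, n_raft),
                "group": "raft",
            }))
            remaining -= n_raft
        if scenario in ("non_motile_cluster", "mixed") and remaining > 0:
            n_cl = min(12, remaining)
            x0 = field_size * 0.75
            parts.append(pd.DataFrame({
                "x": x0 + 1.5 * np.arange(n_cl),
                "y": np.full(n_cl, field_size * 0.75),
                "orientation": rng.uniform(0, np.pi, n_cl),
                "speed": rng.uniform(0.0, 2.0, n_cl),
                "group": "cluster",
            }))
            remaining -= n_cl
        if remaining > 0:
            # background kept > 45 µm from the constructed groups so it
            # cannot enter their 30 µm neighbourhoods
            bg = []
            exclusions = []
            if scenario in ("raft", "mixed"):
                exclusions.append((field_size * 0.25, field_size * 0.25, 45.0))
            if scenario in ("non_motile_cluster", "mixed"):
                exclusions.append((field_size * 0.75, field_size * 0.75, 45.0))
            while len(bg) < remaining:
                cand = rng.uniform(0, field_size, 2)
                if all((cand[0] - ex)**2 + (cand[1] - ey)**2 > r**2
                       for ex, ey, r in exclusions):
                    bg.append(cand)
            bg = np.array(bg)
            parts.append(pd.DataFrame({
                "x": bg[:, 0], "y": bg[:, 1],
                "orientation": rng.uniform(0, np.pi, remaining),
                "speed": rng.uniform(12, 30, remaining),
                "group": "background",
            }))
        if parts:
            df = pd.concat(parts, ignore_index=True)
        else:
            df = pd.DataFrame(columns=["x", "y", "orientation", "speed", "group"])
        df.insert(0, "frame", f)
        df["area"] = rng.uniform(2.0, 4.0, len(df)) if len(df) else []
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["frame", "x", "y", "orientation", "speed", "group", "area"])


def gen_metabolite_series(positions: np.ndarray, front_passage_times: np.ndarray,
                          secretion_rate: float, consumption_delay: float,
                          noise: float = 0.0, times: np.ndarray | None = None,
                          seed: int = 0, compound: str = "pyruvate",
                          n_replicates: int = 4
                          ) -> tuple[list[MetaboliteSeries], dict[float, float]]:
    """Secrete-then-consume kinetics with front-arrival shifts.

    Each position's concentration rises logistically after the front
    passes, peaks ``consumption_delay`` hours later and decays
    symmetrically: c(t) = A σ((t-ta)/w) σ((ta+2d-t)/w) with d the delay
    and w = d/4.  Peak times are therefore ordered with front arrival.

    Returns the series plus a bookkeeping map position -> true peak time.
    """
    positions = np.asarray(positions, float)
    front_passage_times = np.asarray(front_passage_times, float)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be sorted ascending")
    if secretion_rate < 0 or consumption_delay <= 0:
        raise ValueError("rates must be nonnegative, delay positive")
    if times is None:
        times = np.arange(0.0, front_passage_times.max() + 4 * consumption_delay, 0.5)
    rng = np.random.default_rng(seed)
    w = consumption_delay / 4.0
    series, peaks = [], {}
    for pos, ta in zip(positions, front_passage_times):
        rise = 1.0 / (1.0 + np.exp(-(times - ta) / w))
        fall = 1.0 / (1.0 + np.exp(-((ta + 2 * consumption_delay) - times) / w))
        c = secretion_rate * rise * fall
        reps = np.repeat(c[:, None], n_replicates, axis=1)
        if noise > 0:
            reps = reps + rng.normal(0.0, noise, reps.shape)
        reps = np.clip(reps, 0.0, None)
        series.append(MetaboliteSeries(compound, float(pos), times, reps))
        peaks[float(pos)] = float(ta + consumption_delay)
    return series, peaks
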