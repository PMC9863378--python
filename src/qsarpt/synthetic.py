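"""Synthetic study generator: chromatograms, descriptor matrices and
replicate clearance tables from a planted linear model.

Peaks are exponentially modified Gaussians (EMG) — a Gaussian of width
``sigma`` convolved with an exponential decay of time constant ``tau`` — the
standard model for tailed chromatographic peaks, whose tailing and asymmetry
grow monotonically with tau/sigma.  Clearance indices are generated per
replicate as

    CI_ij = intercept + sum_k beta_k z_k(i) + eps_ij,   eps ~ N(0, noise_sd)

with z the autoscaled planted descriptors, truncated strictly positive so
1/Y and 1/Y² regression weights stay finite.

The default study mirrors the shape of the real data set: 15 compounds,
5 replicates, 104 chromatographic + 50 molecular descriptor slots, compound
mean CI spanning roughly 0.06-0.85, and two compounds displaced in
descriptor space to exercise high-leverage pinning.  It does not attempt to
simulate real retention physics or bisphenol chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UnknownDescriptorError
from .io import (
    ClearanceTable,
    DescriptorMatrix,
    DescriptorSchema,
    PublishedModel,
    build_chrom_schema,
    build_molecular_schema,
)
from .peaks import ChromTrace, traces_to_matrix
from .selection import scale_matrix

def _all_conditions() -> tuple[tuple[str, str], ...]:
    from .io import CHROM_COLUMNS, SOLVENTS

    return tuple((c, s) for c in CHROM_COLUMNS for s in SOLVENTS)


@dataclass(frozen=True)
class EMGParams:
    """One peak: apex location tr0 (min), Gaussian sigma (min), exponential
    tau (min), amplitude (area units)."""

    tr0: float
    sigma: float
    tau: float
    amplitude: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


def emg_signal(t: np.ndarray, p: EMGParams) -> np.ndarray:
    """Analytic EMG profile (Gaussian when tau = 0)."""
    if p.tau == 0:
        return p.amplitude * stats.norm.pdf(t, loc=p.tr0, scale=p.sigma)
    K = p.tau / p.sigma
    return p.amplitude * stats.exponnorm.pdf(t, K, loc=p.tr0, scale=p.sigma)


# Planted model used by the default study: six peak-shape descriptors in
# scaled space, coefficients sized so compound means span the observed CI
# range while staying positive.
DEFAULT_PLANTED = PublishedModel(
    name="planted",
    intercept=0.44,
    coefficients=(
        ("T3A2", -0.12),
        ("PFPA7", 0.06),
        ("CC18A7", 0.07),
        ("C8M7", 0.10),
        ("PFPM7", 0.06),
        ("CNM8", 0.09),
    ),
)


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_compounds: int = 15
    conditions: tuple[tuple[str, str], ...] = field(default_factory=_all_conditions)
    peak_params: dict = field(default_factory=dict)  # (compound, col, solv) -> EMGParams
    sampling_rate: float = 400.0  # points per minute
    detector_noise_sd: float = 0.0
    window: tuple[float, float] | None = None  # explicit time window override
    planted: PublishedModel = DEFAULT_PLANTED
    n_replicates: int = 5
    replicate_noise_sd: float = 0.08
    correlation_blocks: tuple = (
        (("LP1", "LP2", "CD1"), 0.85),
        (("MT5", "MT6"), 0.80),
        (("DE1", "DE2", "DE3"), 0.85),
    )  # (codes, target pairwise correlation r)

    def __post_init__(self):
        if self.replicate_noise_sd < 0 or self.detector_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def compound_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1:02d}" for i in range(self.n_compounds))


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A fully parameterised study configuration with realistic peak shapes.

    Per condition: a base retention (2.5-8.5 min), base width and tailing
    ratio; per compound: a shared retention propensity plus condition-level
    jitter.  The two last compounds are descriptor-space outliers, displaced
    on the PFP asymmetry slots (near-symmetric peaks) and on the T3 width /
    C8 asymmetry slots respectively.
    """
    cfg = SyntheticConfig(seed=seed, **overrides)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    compounds = cfg.compound_ids
    n = len(compounds)
    # shared compound-level propensities: retention (hydrophobicity-like),
    # band broadening and tailing (H-bonding-like) act across all phases,
    # with condition-level idiosyncrasy on top — the premise of peak-shape
    # descriptors is precisely that these propensities encode structure
    affinity = rng.normal(0.0, 0.8, size=n)
    broadening = rng.normal(0.0, 0.08, size=n)  # log-sigma loading
    # tailing propensity correlates with retention (H-bonding drives both)
    tailing_prop = 0.12 * (
        0.5 * affinity / 0.8 + np.sqrt(0.75) * rng.normal(size=n)
    )
    params = {}
    for col, solv in cfg.conditions:
        tr_base = rng.uniform(2.5, 8.5)
        tr_gain = rng.uniform(0.4, 1.2)
        sigma_base = rng.uniform(0.05, 0.09)
        ratio_base = rng.uniform(0.8, 1.6)
        for i, comp in enumerate(compounds):
            tr0 = tr_base + tr_gain * affinity[i] + rng.normal(0, 0.3)
            tr0 = max(tr0, 0.8)
            sigma = sigma_base * float(np.exp(broadening[i] + rng.normal(0, 0.15)))
            ratio = ratio_base * float(np.exp(tailing_prop[i] + rng.normal(0, 0.26)))
            params[(comp, col, solv)] = EMGParams(
                tr0=tr0, sigma=sigma, tau=ratio * sigma, amplitude=rng.uniform(0.5, 2.0)
            )
    if n >= 4:
        # Two descriptor-space outliers, each displaced on three planted
        # slots (heavily tailed peaks / tripled Gaussian width); coefficient
        # signs of the planted model keep their CI inside the usual range.
        o1, o2 = compounds[-2], compounds[-1]
        displacements = {
            (o1, "PFP", "A"): "tail",
            (o1, "PFP", "M"): "tail",
            (o1, "T3", "A"): "wide",
            (o2, "T3", "A"): "wide",
            (o2, "C8", "M"): "tail",
            (o2, "CC18", "A"): "tail",
        }
        for (comp, col, solv), kind in displacements.items():
            if (col, solv) not in cfg.conditions:
                continue
            p = params[(comp, col, solv)]
            if kind == "tail":
                params[(comp, col, solv)] = EMGParams(p.tr0, p.sigma, 8.0 * p.tau, p.amplitude)
            else:
                params[(comp, col, solv)] = EMGParams(p.tr0, 3.0 * p.sigma, p.tau, p.amplitude)
    cfg.peak_params = params
    return cfg


def generate_traces(cfg: SyntheticConfig) -> list[ChromTrace]:
    """Render every configured peak as a sampled trace (deterministic in seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    traces = []
    for (comp, col, solv), p in cfg.peak_params.items():
        lo = p.tr0 - 5.0 * p.sigma
        hi = p.tr0 + 5.0 * p.sigma + 12.0 * p.tau
        if cfg.window is not None:
            wlo, whi = cfg.window
            if wlo > p.tr0 - 3 * p.sigma or whi < p.tr0 + 3 * p.sigma + 5 * p.tau:
                raise ValueError(
                    f"window {cfg.window} does not cover the peak of {comp} on ({col},{solv})"
                )
            lo, hi = wlo, whi
        n_pts = max(int(np.ceil((hi - lo) * cfg.sampling_rate)) + 1, 16)
        t = np.linspace(lo, hi, n_pts)
        s = emg_signal(t, p)
        if cfg.detector_noise_sd > 0:
            s = s + rng.normal(0, cfg.detector_noise_sd * s.max(), size=s.shape)
        traces.append(
            ChromTrace(time=t, signal=s, compound_id=comp, column_code=col, solvent_code=solv)
        )
    return traces


def correlated_matrix(
    compound_ids,
    schema: DescriptorSchema,
    blocks=(),
    seed: int = 0,
) -> DescriptorMatrix:
    """Random descriptor matrix with exact in-sample correlation blocks.

    Within each block the first code is the anchor; the others are built as
    r * anchor + sqrt(1 - r²) * residual with the residual orthogonalised
    in-sample, so each pair (anchor, member) has sample correlation exactly
    r.  Columns are then given arbitrary raw location/scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    n = len(compound_ids)
    p = len(schema)
    G = rng.normal(size=(n, p))
    codes = list(schema.codes)

    def std(v):
        v = v - v.mean()
        return v / v.std(ddof=1)

    for members, r in blocks:
        for m in members:
            if m not in codes:
                raise UnknownDescriptorError(m)
        anchor = std(G[:, codes.index(members[0])])
        for m in members[1:]:
            j = codes.index(m)
            e = G[:, j] - G[:, j].mean()
            e = e - (e @ anchor) / (anchor @ anchor) * anchor
            e = std(e)
            G[:, j] = r * anchor + np.sqrt(1 - r**2) * e
        G[:, codes.index(members[0])] = anchor
    loc = rng.uniform(-5, 5, size=p)
    sc = rng.uniform(0.5, 3.0, size=p)
    return DescriptorMatrix(list(compound_ids), schema, G * sc + loc)


def plant_ci(
    X: DescriptorMatrix,
    planted: PublishedModel,
    n_replicates: int = 5,
    noise_sd: float = 0.08,
    seed: int = 0,
) -> ClearanceTable:
    """Replicate clearance indices from a linear model in scaled space.

    Values at or below 0.01 are resampled (fresh noise draw) and, failing
    that, clamped just above 0.01 — a generator property keeping reciprocal
    regression weights finite, not a modelling assumption.
    """
    for code, _ in planted.coefficients:
        if code not in X.schema:
            raise UnknownDescriptorError(code)
    Xs = scale_matrix(X)
    Z = Xs.columns(planted.codes)
    betas = np.array([b for _, b in planted.coefficients])
    mean = planted.intercept + Z @ betas
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    rows = []
    for i, comp in enumerate(X.compound_ids):
        for rep in range(1, n_replicates + 1):
            ci = mean[i] + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            tries = 0
            while ci <= 0.01 and tries < 1000 and noise_sd > 0:
                ci = mean[i] + rng.normal(0, noise_sd)
                tries += 1
            if ci <= 0.01:
                ci = 0.01 + 1e-6
            rows.append({"compound_id": comp, "replicate_id": rep, "ci": float(ci)})
    return ClearanceTable(pd.DataFrame(rows))


@dataclass
class StudyBundle:
    traces: list[ChromTrace]
    molecular: DescriptorMatrix
    chromatographic: DescriptorMatrix
    clearance: ClearanceTable
    planted: PublishedModel
    config: SyntheticConfig

    @property
    def reference_compound(self) -> str:
        return self.config.compound_ids[0]


def paperlike_study(seed: int = 0, **overrides) -> StudyBundle:
    """A complete synthetic study shaped like the real data set.

    15 compounds x 5 replicates; a 15 x 104 chromatographic matrix measured
    from generated EMG traces (first compound is the k' reference); a
    15 x 50 molecular-like matrix with correlated blocks; replicate CI from
    the planted six-descriptor model.
    """
    cfg = default_config(seed=seed, **overrides)
    traces = generate_traces(cfg)
    chrom = traces_to_matrix(traces, cfg.compound_ids[0], build_chrom_schema())
    mol = correlated_matrix(
        cfg.compound_ids, build_molecular_schema(), cfg.correlation_blocks, seed=cfg.seed
    )
    clearance = plant_ci(
        chrom, cfg.planted, cfg.n_replicates, cfg.replicate_noise_sd, seed=cfg.seed
    )
    return StudyBundle(
        traces=traces,
        molecular=mol,
        chromatographic=chrom,
        clearance=clearance,
        planted=cfg.planted,
        config=cfg,
    )
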