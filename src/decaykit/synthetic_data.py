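"""Synthetic transcription shut-off time courses with known ground truth.

The generator emulates a one-color microarray decay experiment: transcription
is blocked at t=0 and per-transcript intensity is measured at a handful of
later time points in two cell states (proliferating ``P`` and 7-day
contact-inhibited ``CI7``), with two biological replicates per state.
Exponential genes follow first-order kinetics A(t) = A0 * exp(-k t); a
configurable fraction carries a condition-dependent decay constant, and
another fraction violates log-linearity (flat or biphasic profiles) to
exercise the goodness-of-fit filter.  Noise is additive on natural-log
intensities (multiplicative on intensities), with a per-replicate batch
offset (each biological replicate is one cell batch measured in both
states) standing in for culture/labelling effects, and non-decaying
spike-in rows standing in for the external hybridization controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import log

import numpy as np
import pandas as pd

from .io_formats import (
    COND_COL,
    REP_COL,
    TIME_COL,
    GeneSetCollection,
    TimeCourseDataset,
    sample_name,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_timecourse",
    "simulate_gene_sets",
    "simulate_expression_ratios",
]

LN2 = log(2.0)


@dataclass
class SimulationConfig:
    """Parameters of the simulated shut-off experiment.

    Baseline half-lives are lognormal with median ``exp(halflife_log_mean)``
    minutes.  The default median of 240 min (4 h) with log-SD 0.75 spans
    roughly 50 min to 20 h over +/-2 SD, matching the dynamic range a
    transcription-inhibitor time course out to 8 h can resolve.  Differential
    genes get ``k_CI7 = k_P * 2**(s * differential_log2_effect)`` with the
    sign ``s`` randomized per gene (sign-balanced) unless ``effect_sign`` is
    fixed.  Non-exponential genes are split between flat profiles (no decay)
    and biphasic decay (fast then slow, breaking at the second positive time
    point) by ``nonexponential_flat_frac``.
    """

    n_genes: int = 12000
    time_points_min: list[float] = field(default_factory=lambda: [0.0, 120.0, 240.0, 480.0])
    n_replicates: int = 2
    conditions: tuple[str, str] = ("P", "CI7")
    halflife_log_mean: float = log(240.0)
    halflife_log_sd: float = 0.75
    frac_differential: float = 0.06
    differential_log2_effect: float = 1.0
    effect_sign: int | None = None  # None = randomized per gene; +1/-1 fixes it
    frac_nonexponential: float = 0.40
    nonexponential_flat_frac: float = 0.5
    noise_sd: float = 0.2
    replicate_effect_sd: float = 0.1
    baseline_log_mean: float = log(1000.0)
    baseline_log_sd: float = 1.0
    spikein_level: float = 1000.0
    n_spikeins: int = 10
    detection_floor: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be a positive count")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        t = list(self.time_points_min)
        if len(t) < 2 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("time_points_min must be strictly increasing")
        if any(x < 0 for x in t):
            raise ValueError("time_points_min must be non-negative")
        for name in ("frac_differential", "frac_nonexponential", "nonexponential_flat_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_differential + self.frac_nonexponential > 1.0 + 1e-12:
            raise ValueError("frac_differential + frac_nonexponential must be <= 1")
        if len(self.conditions) != 2:
            raise ValueError("conditions must be an ordered pair of state labels")
        for name in ("noise_sd", "replicate_effect_sd", "halflife_log_sd", "baseline_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.effect_sign not in (None, 1, -1):
            raise ValueError("effect_sign must be None, +1 or -1")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated run, aligned to gene ids.

    ``table`` has one row per (non-spike-in) gene with columns ``k_P``,
    ``k_CI7`` (per-minute decay constants on the natural-log scale), ``A0``,
    ``differential`` and ``nonexponential`` flags, and ``nonexp_shape``
    ('' / 'flat' / 'biphasic').  Planted gene-set memberships and true log2
    expression ratios are attached by the downstream generators.
    """

    table: pd.DataFrame
    config: SimulationConfig

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def delta(self) -> pd.Series:
        """True decay difference k_P - k_CI7 (positive = stabilized in CI7)."""
        return self.table["k_P"] - self.table["k_CI7"]


def simulate_timecourse(config: SimulationConfig) -> tuple[TimeCourseDataset, SyntheticTruth]:
    """Simulate a two-condition shut-off time course with known truth.

    Returns the dataset (including flagged spike-in rows) and the aligned
    ground-truth table.  Identical config (including seed) gives bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = pd.Index([f"G{i:05d}" for i in range(n)], name="gene")

    # baseline kinetics
    halflife = np.exp(rng.normal(config.halflife_log_mean, config.halflife_log_sd, n))
    k_base = LN2 / halflife
    a0 = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, n))

    # gene classes: differential / non-exponential / plain exponential
    n_diff = int(round(config.frac_differential * n))
    n_nonexp = int(round(config.frac_nonexponential * n))
    if n_diff + n_nonexp > n:
        n_nonexp = n - n_diff
    perm = rng.permutation(n)
    diff_idx = perm[:n_diff]
    nonexp_idx = perm[n_diff:n_diff + n_nonexp]

    differential = np.zeros(n, dtype=bool)
    differential[diff_idx] = True
    nonexponential = np.zeros(n, dtype=bool)
    nonexponential[nonexp_idx] = True

    if config.effect_sign is None:
        signs = rng.choice([-1.0, 1.0], size=n)
    else:
        signs = np.full(n, float(config.effect_sign))
    k_p = k_base.copy()
    k_ci7 = k_base.copy()
    k_ci7[differential] = k_base[differential] * 2.0 ** (
        signs[differential] * config.differential_log2_effect
    )

    shape = np.array([""] * n, dtype=object)
    is_flat = rng.random(n_nonexp) < config.nonexponential_flat_frac
    shape[nonexp_idx[is_flat]] = "flat"
    shape[nonexp_idx[~is_flat]] = "biphasic"
    flat = shape == "flat"
    biphasic = shape == "biphasic"
    k_p[flat] = 0.0
    k_ci7[flat] = 0.0

    # sample design
    times = np.asarray(config.time_points_min, dtype=float)
    rows = []
    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            for t in times:
                rows.append((sample_name(cond, rep, t), t, cond, rep))
    design = pd.DataFrame(
        rows, columns=["sample", TIME_COL, COND_COL, REP_COL]
    ).set_index("sample")
    samples = design.index
    n_samples = len(samples)

    # noiseless ln-intensity per gene x sample
    k_by_cond = {config.conditions[0]: k_p, config.conditions[1]: k_ci7}
    ln_i = np.empty((n, n_samples))
    t_break = times[1] if len(times) > 1 else times[-1]
    for j, s in enumerate(samples):
        t = design.loc[s, TIME_COL]
        k = k_by_cond[design.loc[s, COND_COL]]
        ln_i[:, j] = np.log(a0) - k * t
        if biphasic.any():
            # fast decay (4x) up to the second time point, then slow (x/4)
            kb = k[biphasic]
            lnb = np.where(
                t <= t_break,
                np.log(a0[biphasic]) - 4.0 * kb * t,
                np.log(a0[biphasic]) - 4.0 * kb * t_break - 0.25 * kb * (t - t_break),
            )
            ln_i[biphasic, j] = lnb

    # biological-replicate (batch) offsets: one per replicate id, shared by
    # both conditions' series of that batch, plus per-observation noise
    rep_offsets = {
        rep: rng.normal(0.0, config.replicate_effect_sd)
        for rep in range(1, config.n_replicates + 1)
    }
    offsets = np.array([rep_offsets[design.loc[s, REP_COL]] for s in samples])
    ln_i = ln_i + offsets[None, :]
    if config.noise_sd > 0:
        ln_i = ln_i + rng.normal(0.0, config.noise_sd, size=ln_i.shape)
    intensities = np.exp(ln_i)

    # spike-in rows: constant level, sharing array offsets and noise
    if config.n_spikeins > 0:
        spike_ln = np.broadcast_to(
            np.log(config.spikein_level) + offsets[None, :],
            (config.n_spikeins, n_samples),
        ).copy()
        if config.noise_sd > 0:
            spike_ln = spike_ln + rng.normal(
                0.0, config.noise_sd, size=(config.n_spikeins, n_samples)
            )
        spike = np.exp(spike_ln)
        spike_genes = pd.Index([f"SPIKE{i:02d}" for i in range(config.n_spikeins)])
        mat = pd.DataFrame(
            np.vstack([intensities, spike]),
            index=genes.append(spike_genes),
            columns=samples,
        )
        spike_flags = pd.Series(
            [False] * n + [True] * config.n_spikeins, index=mat.index
        )
    else:
        mat = pd.DataFrame(intensities, index=genes, columns=samples)
        spike_flags = pd.Series(False, index=mat.index)

    if config.detection_floor is not None:
        mat = mat.where(mat >= config.detection_floor)

    truth = pd.DataFrame(
        {
            "k_P": k_p,
            "k_CI7": k_ci7,
            "A0": a0,
            "differential": differential,
            "nonexponential": nonexponential,
            "nonexp_shape": shape,
        },
        index=genes,
    )
    return TimeCourseDataset(mat, design, spike_flags), SyntheticTruth(truth, config)


def simulate_gene_sets(
    truth: SyntheticTruth,
    n_sets: int = 50,
    set_size: int = 50,
    n_planted: int = 1,
    seed: int = 0,
    planted_direction: int = 1,
) -> GeneSetCollection:
    """Draw null gene sets plus planted "regulated target" sets.

    Planted sets are drawn from differential genes of one stability
    direction (``planted_direction=+1``: k_P > k_CI7, i.e. stabilized with
    quiescence, the miR-29-like case), topped up with uniform draws if the
    directional pool is smaller than ``set_size``.  Null sets are uniform
    draws from the whole gene universe.  The collection records which set
    names are planted.
    """
    rng = np.random.default_rng(seed)
    universe = list(truth.genes)
    if set_size > len(universe):
        raise ValueError(f"set_size {set_size} exceeds universe size {len(universe)}")
    if n_planted > n_sets:
        raise ValueError("n_planted cannot exceed n_sets")

    delta = truth.delta()
    pool = [
        g
        for g in universe
        if truth.table.loc[g, "differential"] and planted_direction * delta[g] > 0
    ]
    others = [g for g in universe if g not in set(pool)]

    sets: dict[str, list[str]] = {}
    annotations: dict[str, str] = {}
    planted: set[str] = set()
    for i in range(n_planted):
        take = min(set_size, len(pool))
        members = list(rng.choice(pool, size=take, replace=False)) if take else []
        if take < set_size:
            members += list(rng.choice(others, size=set_size - take, replace=False))
        name = f"planted_set_{i:02d}"
        sets[name] = sorted(members)
        annotations[name] = "planted regulated-target set"
        planted.add(name)
    for i in range(n_sets - n_planted):
        name = f"null_set_{i:03d}"
        sets[name] = sorted(rng.choice(universe, size=set_size, replace=False))
        annotations[name] = "uniform null set"
    return GeneSetCollection(universe, sets, annotations, planted)


def simulate_expression_ratios(
    truth: SyntheticTruth,
    coupling: float = 0.5,
    lfc_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate steady-state log2(CI7/P) ratios partially coupled to stability.

    A ``coupling`` fraction of differential genes get ratios whose sign
    matches their stabilization direction (stabilized in CI7, i.e.
    k_P > k_CI7, implies a positive log2 ratio); all remaining ratios are
    independent N(0, lfc_sd^2) draws.  Returns a one-column table
    (``log2fc_CI7``) indexed by gene, which is also attached to the truth
    table as ``true_log2fc``.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError(f"coupling must lie in [0, 1], got {coupling}")
    if lfc_sd < 0:
        raise ValueError("lfc_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(truth.genes)
    lfc = rng.normal(0.0, lfc_sd, n)
    delta = truth.delta().to_numpy()
    diff = truth.table["differential"].to_numpy()
    coupled = diff & (rng.random(n) < coupling)
    lfc[coupled] = np.sign(delta[coupled]) * np.abs(lfc[coupled])
    table = pd.DataFrame({"log2fc_CI7": lfc}, index=truth.genes)
    truth.table["true_log2fc"] = lfc
    return table


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (e.g. parsed YAML)."""
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg


def config_to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)
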