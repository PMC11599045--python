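"""Synthetic time-course experiments and metabolome panels with known truth.

The generator emulates a three-condition LPS-stimulation design
(Norm / AHyp / CHyp) sampled on a 0-24 h grid with two replicates. Each
gene gets a baseline level drawn log-normally (FPKM scale), a shared
induction curve — value 1 at t = 0, linear rise to ``peak_fold`` at
``peak_time_h``, exponential relaxation back toward baseline afterwards —
and a designed class effect: depending on its class the CHyp and/or AHyp
trajectory is multiplied by 2^effect (up classes) or 2^-effect (down
classes). Observed replicate values multiply the trajectory by 2^eps with
eps ~ Normal(0, noise_sd_log2^2).

All randomness flows from the single spec seed through a counter-based
substream per gene (one generator keyed by (seed, gene index)), so adding
genes never perturbs the values of existing ones and identical seeds give
byte-identical outputs.

The metabolome generator plants a chosen number of truly differential
metabolites (group mean shifted by 2^effect) inside a null panel sharing
group means, with the same multiplicative noise model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MetaboliteTable, TimeCourseExperiment

__all__ = [
    "SyntheticSpec",
    "simulate_timecourse",
    "simulate_metabolome",
    "simulate_correlated_contrasts",
]

CONDITIONS = ("Norm", "AHyp", "CHyp")

DEFAULT_CLASS_COUNTS = {
    "ChH": 60,
    "AcH": 60,
    "HH": 60,
    "ChL": 60,
    "AcL": 60,
    "LL": 60,
    "NC": 640,
}

# (chronic multiplier sign, acute multiplier sign) in log2 units per class
_CLASS_SIGNS = {
    "ChH": (1, 0),
    "AcH": (0, 1),
    "HH": (1, 1),
    "ChL": (-1, 0),
    "AcL": (0, -1),
    "LL": (-1, -1),
    "NC": (0, 0),
}


@dataclass
class SyntheticSpec:
    """Design of a synthetic LPS time-course experiment.

    Parameters
    ----------
    class_counts
        Genes per response class (ChH, AcH, HH, ChL, AcL, LL, NC).
    effect_log2
        Designed |log2| effect applied to the perturbed condition(s) of
        each non-NC class (log2 units).
    baseline_log_mean, baseline_log_sd
        Natural-log mean/sd of the log-normal baseline expression (FPKM).
    peak_time_h, decay_per_h, peak_fold
        Induction kinetics: time of peak (h), exponential relaxation rate
        after the peak (1/h), and fold induction at the peak.
    noise_sd_log2
        Replicate noise sd in log2 units (multiplicative).
    time_grid_h
        Sampling times in hours; must include 0.
    n_replicates
        Replicates per condition and time point.
    seed
        Master seed; recorded in all outputs.
    """

    class_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    effect_log2: float = 2.0
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    peak_time_h: float = 4.0
    decay_per_h: float = 0.15
    peak_fold: float = 8.0
    noise_sd_log2: float = 0.25
    time_grid_h: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 24.0)
    n_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.class_counts) - set(_CLASS_SIGNS)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if not np.isfinite(self.effect_log2):
            raise ValueError("effect size must be finite")
        if 0.0 not in self.time_grid_h:
            raise ValueError("time grid must include 0")
        if len(set(self.time_grid_h)) < 2:
            raise ValueError("time grid needs >= 2 distinct points")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")
        if self.peak_time_h <= 0 or self.peak_fold < 1 or self.decay_per_h < 0:
            raise ValueError("invalid induction kinetics")
        if self.noise_sd_log2 < 0 or self.baseline_log_sd < 0:
            raise ValueError("spreads must be >= 0")

    def n_genes(self) -> int:
        return sum(self.class_counts.values())


def _induction(spec: SyntheticSpec, t: np.ndarray) -> np.ndarray:
    amp = spec.peak_fold - 1.0
    rise = 1.0 + amp * t / spec.peak_time_h
    decay = 1.0 + amp * np.exp(-spec.decay_per_h * (t - spec.peak_time_h))
    return np.where(t <= spec.peak_time_h, rise, decay)


def _sample_frame(spec: SyntheticSpec) -> pd.DataFrame:
    grid = sorted(spec.time_grid_h)
    rows = [
        {
            "sample_id": f"{cond}_t{t:g}_r{rep}",
            "condition": cond,
            "time_h": float(t),
            "replicate": rep,
        }
        for cond in CONDITIONS
        for t in grid
        for rep in range(1, spec.n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def simulate_timecourse(spec: SyntheticSpec) -> tuple[TimeCourseExperiment, pd.DataFrame]:
    """Generate a Norm/AHyp/CHyp time course with designed class truth.

    Returns the experiment plus a truth table (gene_id, class,
    effect_chronic, effect_acute, baseline, seed), one row per gene.
    """
    spec.validate()
    samples = _sample_frame(spec)
    grid = np.array(sorted(spec.time_grid_h), dtype=float)
    curve = _induction(spec, grid)

    gene_ids, classes = [], []
    for label in _CLASS_SIGNS:  # fixed label order keeps gene ids stable
        for _ in range(spec.class_counts.get(label, 0)):
            gene_ids.append(f"g{len(gene_ids):05d}")
            classes.append(label)

    n_samples = len(samples)
    t_idx = {t: i for i, t in enumerate(grid)}
    sample_time = samples["time_h"].map(t_idx).to_numpy()
    cond_of = samples["condition"].to_numpy()

    values = np.empty((len(gene_ids), n_samples))
    baselines = np.empty(len(gene_ids))
    truth_rows = []
    for gi, (gid, label) in enumerate(zip(gene_ids, classes)):
        rng = np.random.default_rng([spec.seed, gi])  # per-gene substream
        base = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd)
        baselines[gi] = base
        sc, sa = _CLASS_SIGNS[label]
        eff = {
            "Norm": 1.0,
            "AHyp": 2.0 ** (sa * spec.effect_log2),
            "CHyp": 2.0 ** (sc * spec.effect_log2),
        }
        traj = base * curve[sample_time] * np.array([eff[c] for c in cond_of])
        noise = rng.normal(0.0, spec.noise_sd_log2, n_samples)
        values[gi] = traj * 2.0**noise
        truth_rows.append(
            {
                "gene_id": gid,
                "class": label,
                "effect_chronic": sc * spec.effect_log2,
                "effect_acute": sa * spec.effect_log2,
                "baseline": base,
                "seed": spec.seed,
            }
        )

    exp = TimeCourseExperiment(
        values=pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                            columns=samples["sample_id"]),
        samples=samples,
    )
    return exp, pd.DataFrame(truth_rows)


def simulate_correlated_contrasts(
    n_genes: int,
    r: float,
    effect_sd_log2: float = 1.0,
    noise_sd_log2: float = 0.25,
    seed: int = 0,
    base_spec: SyntheticSpec | None = None,
) -> tuple[TimeCourseExperiment, pd.DataFrame]:
    """Generate an experiment whose designed chronic and acute log2
    effects are bivariate normal with correlation ``r``.

    Used to check that estimated log2 AUC ratios reproduce a designed
    cross-contrast Pearson correlation. Truth columns: gene_id,
    effect_chronic, effect_acute.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must be in [-1, 1]")
    spec = base_spec or SyntheticSpec()
    spec.validate()
    samples = _sample_frame(spec)
    grid = np.array(sorted(spec.time_grid_h), dtype=float)
    curve = _induction(spec, grid)
    t_idx = {t: i for i, t in enumerate(grid)}
    sample_time = samples["time_h"].map(t_idx).to_numpy()
    cond_of = samples["condition"].to_numpy()
    n_samples = len(samples)

    gene_ids = [f"g{gi:05d}" for gi in range(n_genes)]
    values = np.empty((n_genes, n_samples))
    truth_rows = []
    for gi, gid in enumerate(gene_ids):
        rng = np.random.default_rng([seed, 1, gi])
        base = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd)
        z1, z2 = rng.normal(size=2)
        e_c = effect_sd_log2 * z1
        e_a = effect_sd_log2 * (r * z1 + np.sqrt(1.0 - r * r) * z2)
        eff = {"Norm": 1.0, "AHyp": 2.0**e_a, "CHyp": 2.0**e_c}
        traj = base * curve[sample_time] * np.array([eff[c] for c in cond_of])
        values[gi] = traj * 2.0 ** rng.normal(0.0, noise_sd_log2, n_samples)
        truth_rows.append(
            {"gene_id": gid, "effect_chronic": e_c, "effect_acute": e_a}
        )

    exp = TimeCourseExperiment(
        values=pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                            columns=samples["sample_id"]),
        samples=samples,
    )
    return exp, pd.DataFrame(truth_rows)


def simulate_metabolome(
    n_metabolites: int = 60,
    n_true: int = 5,
    effect_log2: float = 3.0,
    n_per_group: int = 3,
    noise_sd_log2: float = 0.25,
    seed: int = 0,
    groups: tuple[str, str] = ("CHyp", "Norm"),
) -> tuple[MetaboliteTable, pd.DataFrame]:
    """Two-group metabolite panel with ``n_true`` planted differentials.

    Null metabolites share the group mean; planted ones have the first
    group's mean multiplied by 2^effect_log2 (sign gives direction).
    Returns the table plus a truth frame (metabolite_id, planted,
    effect_log2).
    """
    if not 0 <= n_true <= n_metabolites:
        raise ValueError("need 0 <= n_true <= n_metabolites")
    if n_per_group < 2:
        raise ValueError("need >= 2 samples per group for testing")
    trt, ref = groups
    sample_ids = [f"{g}_r{i}" for g in groups for i in range(1, n_per_group + 1)]
    group_labels = [g for g in groups for _ in range(n_per_group)]

    mids = [f"met_{i:04d}" for i in range(n_metabolites)]
    values = np.empty((n_metabolites, len(sample_ids)))
    truth_rows = []
    for mi, mid in enumerate(mids):
        rng = np.random.default_rng([seed, 2, mi])
        base = rng.lognormal(2.0, 1.0)
        planted = mi < n_true
        mult = np.array(
            [
                (2.0**effect_log2 if (planted and g == trt) else 1.0)
                for g in group_labels
            ]
        )
        noise = rng.normal(0.0, noise_sd_log2, len(sample_ids))
        values[mi] = base * mult * 2.0**noise
        truth_rows.append(
            {
                "metabolite_id": mid,
                "planted": planted,
                "effect_log2": effect_log2 if planted else 0.0,
            }
        )

    table = MetaboliteTable(
        values=pd.DataFrame(
            values, index=pd.Index(mids, name="metabolite_id"), columns=sample_ids
        ),
        groups=pd.Series(group_labels, index=sample_ids, name="condition"),
    )
    return table, pd.DataFrame(truth_rows)
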