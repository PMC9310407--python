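"""Synthetic bulk RNA-seq experiments and mouse lifespans with planted ground truth.

The generator emulates the two study designs the downstream classifiers expect:

* an *aging-reversal* design — young wild-type, old vehicle-treated and old
  treated groups, where a fraction of genes drift with age and a subset of
  those drifts is pushed back by the treatment; and
* a *factorial* (genotype x treatment) design — wild-type and tissue-specific
  knockout animals, each vehicle- or compound-treated, where a fraction of the
  treatment-responsive genes lose their response in the knockout.

Counts are negative binomial with variance mu + phi * mu**2.  The mean for
gene g in sample s is

    mu_gs = 2**(b_g + shift_gs) * length_kb(g) * libsize(s) / 1e6

so that ``b_g`` is a baseline log2-RPKM and planted effects are log2-unit
shifts, which is what the RPKM -> log2 -> Welch-t pipeline downstream
estimates.  Every draw flows from one :func:`numpy.random.default_rng` seeded
from the spec, so identical specs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "Group",
    "DesignSpec",
    "SurvivalParams",
    "simulate_experiment",
    "simulate_survival",
]

AGING = "aging_direction"
REVERTED = "reverted"
DEPENDENCE = "dependence"
TRT_DIRECTION = "trt_direction"


class DesignError(ValueError):
    """A design/parameter field violates its invariant; message names the field."""


@dataclass(frozen=True)
class Group:
    """One experimental arm: its sample size and the factors that drive effects."""

    label: str
    n: int
    age_months: float
    genotype: str = "WT"      # "WT" or "mcKO"
    treatment: str = "none"   # "none", "Veh" or "Hes"
    tissue: str = "gastrocnemius"


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of a simulated count experiment.

    Fractions are taken of the gene universe (``frac_aging``,
    ``frac_responsive``) or of the aging genes (``frac_reverted``) or of the
    treatment-responsive genes (``frac_dependent``); counts are floored and
    the remainder genes stay unaffected ("none").
    """

    groups: tuple[Group, ...]
    n_genes: int = 2000
    frac_aging: float = 0.1
    frac_reverted: float = 0.5
    frac_dependent: float = 0.8
    frac_responsive: float | None = None
    effect_size: float = 2.0
    dispersion: float = 0.1
    libsize_mean: float = 2.0e7
    libsize_cv: float = 0.2
    length_range_bp: tuple[int, int] = (200, 10_000)
    baseline_log2rpkm_range: tuple[float, float] = (3.0, 8.0)
    reversal_fraction: float = 1.0
    old_age_months: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise DesignError("groups: at least one group is required")
        for g in self.groups:
            if g.n < 2:
                raise DesignError(f"groups[{g.label}].n: need >= 2 samples, got {g.n}")
        if self.n_genes < 1:
            raise DesignError(f"n_genes: must be positive, got {self.n_genes}")
        for name in ("frac_aging", "frac_reverted", "frac_dependent", "reversal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DesignError(f"{name}: must be in [0, 1], got {v}")
        if self.frac_responsive is not None and not 0.0 <= self.frac_responsive <= 1.0:
            raise DesignError(f"frac_responsive: must be in [0, 1], got {self.frac_responsive}")
        if self.effect_size < 0:
            raise DesignError(f"effect_size: must be >= 0, got {self.effect_size}")
        if self.dispersion <= 0:
            raise DesignError(f"dispersion: must be > 0, got {self.dispersion}")
        if self.libsize_mean <= 0:
            raise DesignError(f"libsize_mean: must be > 0, got {self.libsize_mean}")
        if self.libsize_cv < 0:
            raise DesignError(f"libsize_cv: must be >= 0, got {self.libsize_cv}")
        lo, hi = self.length_range_bp
        if lo < 1 or hi < lo:
            raise DesignError(f"length_range_bp: need 1 <= min <= max, got {self.length_range_bp}")

    # -- canonical designs ---------------------------------------------------

    @classmethod
    def aging_reversal(cls, n_per_group: int = 5, tissue: str = "heart", **kw) -> "DesignSpec":
        """Young WT / old WT-Veh / old WT-Hes three-group design."""
        groups = (
            Group("young_WT", n_per_group, age_months=3, treatment="none", tissue=tissue),
            Group("old_WT_Veh", n_per_group, age_months=26, treatment="Veh", tissue=tissue),
            Group("old_WT_Hes", n_per_group, age_months=26, treatment="Hes", tissue=tissue),
        )
        return cls(groups=groups, **kw)

    @classmethod
    def factorial(cls, n_per_group: int = 5, tissue: str = "gastrocnemius", **kw) -> "DesignSpec":
        """WT/knockout x Veh/treated four-group design (no age contrast)."""
        kw.setdefault("frac_aging", 0.0)
        kw.setdefault("frac_responsive", 0.1)
        groups = (
            Group("WT_Veh", n_per_group, age_months=7, genotype="WT", treatment="Veh", tissue=tissue),
            Group("WT_Hes", n_per_group, age_months=7, genotype="WT", treatment="Hes", tissue=tissue),
            Group("mcKO_Veh", n_per_group, age_months=7, genotype="mcKO", treatment="Veh", tissue=tissue),
            Group("mcKO_Hes", n_per_group, age_months=7, genotype="mcKO", treatment="Hes", tissue=tissue),
        )
        return cls(groups=groups, **kw)

    def with_seed(self, seed: int) -> "DesignSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SurvivalParams:
    """Weibull lifespan model; the scale is set so the theoretical median is exact."""

    baseline_median_months: float = 25.95
    treatment_median_shift_months: float = 2.25
    shape: float = 8.0
    max_follow_up_months: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_median_months <= 0:
            raise DesignError(
                f"baseline_median_months: must be > 0, got {self.baseline_median_months}"
            )
        if self.shape <= 0:
            raise DesignError(f"shape: must be > 0, got {self.shape}")
        if self.max_follow_up_months <= 0:
            raise DesignError(
                f"max_follow_up_months: must be > 0, got {self.max_follow_up_months}"
            )
        if self.baseline_median_months + self.treatment_median_shift_months <= 0:
            raise DesignError("treatment_median_shift_months: treated median must stay > 0")


# ---------------------------------------------------------------------------
# truth assignment
# ---------------------------------------------------------------------------

def _assign_truth(spec: DesignSpec, gene_ids: pd.Index) -> pd.DataFrame:
    """Deterministic planted classes: floor rounding, remainder genes 'none'.

    Gene order: aging genes first (up before down, reverted before not),
    then directly treatment-responsive genes, then unaffected genes.
    """
    g = spec.n_genes
    n_aging = math.floor(spec.frac_aging * g)
    n_rev = math.floor(spec.frac_reverted * n_aging)
    n_resp_direct = math.floor((spec.frac_responsive or 0.0) * g)
    if n_aging + n_resp_direct > g:
        raise DesignError("frac_responsive: aging + responsive genes exceed n_genes")

    aging_dir = np.array(["none"] * g, dtype=object)
    # split up/down as evenly as possible, extra gene to "up"
    n_up = (n_aging + 1) // 2
    aging_dir[:n_up] = "up"
    aging_dir[n_up:n_aging] = "down"

    reverted = np.zeros(g, dtype=bool)
    # take reverted genes evenly from the up and down halves
    n_rev_up = min((n_rev + 1) // 2, n_up)
    n_rev_down = min(n_rev - n_rev_up, n_aging - n_up)
    n_rev_up = n_rev - n_rev_down  # top up if the down half was short
    reverted[:n_rev_up] = True
    reverted[n_up : n_up + n_rev_down] = True

    trt_dir = np.array(["none"] * g, dtype=object)
    # reverted genes respond opposite to their aging drift
    trt_dir[reverted & (aging_dir == "up")] = "down"
    trt_dir[reverted & (aging_dir == "down")] = "up"
    # directly responsive genes (factorial designs) sit after the aging block
    n_dir_up = (n_resp_direct + 1) // 2
    trt_dir[n_aging : n_aging + n_dir_up] = "up"
    trt_dir[n_aging + n_dir_up : n_aging + n_resp_direct] = "down"

    responsive = trt_dir != "none"
    dependence = np.array(["none"] * g, dtype=object)
    resp_idx = np.flatnonzero(responsive)
    n_dep = math.floor(spec.frac_dependent * resp_idx.size)
    dependence[resp_idx[:n_dep]] = "dependent"
    dependence[resp_idx[n_dep:]] = "independent"

    return pd.DataFrame(
        {AGING: aging_dir, REVERTED: reverted, DEPENDENCE: dependence, TRT_DIRECTION: trt_dir},
        index=gene_ids,
    )


def _log2_shift_matrix(spec: DesignSpec, truth: pd.DataFrame) -> np.ndarray:
    """Per-gene x per-sample planted log2 shifts implied by the truth table."""
    sign = {"up": 1.0, "down": -1.0, "none": 0.0}
    beta_age = spec.effect_size * truth[AGING].map(sign).to_numpy(float)
    # reversal shift: applies only in old treated groups, opposes the aging drift
    beta_rev = -spec.reversal_fraction * beta_age * truth[REVERTED].to_numpy()
    # direct treatment shift: applies in any treated group
    direct = (truth[TRT_DIRECTION] != "none") & ~truth[REVERTED]
    beta_trt = spec.effect_size * truth[TRT_DIRECTION].map(sign).to_numpy(float) * direct.to_numpy()
    dependent = (truth[DEPENDENCE] == "dependent").to_numpy()

    cols = []
    for grp in spec.groups:
        old = grp.age_months >= spec.old_age_months
        treated = grp.treatment == "Hes"
        ko = grp.genotype == "mcKO"
        shift = np.zeros(spec.n_genes)
        if old:
            shift = shift + beta_age
        if treated:
            trt = beta_trt.copy()
            if old:
                trt = trt + beta_rev
            if ko:
                trt = np.where(dependent, 0.0, trt)
            shift = shift + trt
        cols.extend([shift] * grp.n)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_experiment(
    spec: DesignSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a count matrix plus annotation, sample sheet and truth labels.

    Returns
    -------
    counts : DataFrame, genes x samples, nonnegative integers
    annotation : DataFrame with columns ``gene_id``, ``length_bp``
    sample_sheet : DataFrame with sample_id, group, age_months, genotype,
        treatment, tissue
    truth : DataFrame indexed by gene_id with the planted class of each gene
        (aging_direction, reverted, dependence, trt_direction)
    """
    rng = np.random.default_rng(spec.seed)
    g = spec.n_genes
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(g)], name="gene_id")

    truth = _assign_truth(spec, gene_ids)
    shifts = _log2_shift_matrix(spec, truth)

    lo, hi = spec.baseline_log2rpkm_range
    baseline = rng.uniform(lo, hi, size=g)
    lengths = rng.integers(spec.length_range_bp[0], spec.length_range_bp[1] + 1, size=g)

    n_samples = sum(grp.n for grp in spec.groups)
    if spec.libsize_cv > 0:
        sigma2 = math.log1p(spec.libsize_cv**2)
        mu_ln = math.log(spec.libsize_mean) - sigma2 / 2.0
        libsizes = rng.lognormal(mu_ln, math.sqrt(sigma2), size=n_samples)
    else:
        libsizes = np.full(n_samples, spec.libsize_mean)

    length_kb = lengths / 1000.0
    mu = (
        np.exp2(baseline[:, None] + shifts)
        * length_kb[:, None]
        * libsizes[None, :]
        / 1e6
    )
    r = 1.0 / spec.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    sample_ids, rows = [], []
    for grp in spec.groups:
        for i in range(grp.n):
            sid = f"{grp.label}_{i + 1}"
            sample_ids.append(sid)
            rows.append(
                dict(
                    sample_id=sid,
                    group=grp.label,
                    age_months=grp.age_months,
                    genotype=grp.genotype,
                    treatment=grp.treatment,
                    tissue=grp.tissue,
                )
            )

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    annotation = pd.DataFrame({"gene_id": gene_ids, "length_bp": lengths}).reset_index(drop=True)
    sheet = pd.DataFrame(rows)
    return counts_df, annotation, sheet, truth


def simulate_survival(
    n_control: int,
    n_treated: int,
    params: SurvivalParams,
    arms: tuple[str, str] = ("Veh", "Hes"),
) -> pd.DataFrame:
    """Weibull lifespans for a control and a treated arm.

    The scale of each arm is chosen so the theoretical median equals
    ``baseline_median_months`` (control) or baseline + shift (treated).
    Lifetimes beyond ``max_follow_up_months`` are censored there (event=0).
    """
    if n_control < 1 or n_treated < 1:
        raise DesignError(f"n per arm: must be >= 1, got ({n_control}, {n_treated})")
    rng = np.random.default_rng(params.seed)
    medians = {
        arms[0]: params.baseline_median_months,
        arms[1]: params.baseline_median_months + params.treatment_median_shift_months,
    }
    ns = {arms[0]: n_control, arms[1]: n_treated}
    frames = []
    for arm in arms:
        scale = medians[arm] / math.log(2) ** (1.0 / params.shape)
        t = scale * rng.weibull(params.shape, size=ns[arm])
        event = t <= params.max_follow_up_months
        t = np.minimum(t, params.max_follow_up_months)
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": [f"{arm}_{i + 1}" for i in range(ns[arm])],
                    "arm": arm,
                    "time_months": t,
                    "event": event.astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
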