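"""Mutant-versus-sibling screening statistics.

The screen compares homozygous mutants against their siblings (wild types
plus heterozygotes from the same incross) over the 94-metric vector:

1. per-metric two-tailed, unpaired Student's (pooled-variance) t tests
   within each of two independent experiments;
2. a reproducibility filter keeping metrics with p < 0.05 in both;
3. within-experiment sibling normalization (divide every value by the
   experiment's mean sibling value) to absorb run-to-run variation,
   followed by pooling across experiments;
4. Bonferroni-corrected testing of the pooled data at p < 0.05/94, with
   effect sizes expressed as the mutant−sibling mean difference in sibling
   standard deviations (the heatmap scale).

Missing values are dropped pairwise per metric and never imputed; a metric
whose sibling mean is zero cannot be normalized and is excluded from
pooling with a flag.  For lines with gross homozygous defects the contrast
can instead compare heterozygotes to wild types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastSpec", "ExperimentData", "ScreenResult",
    "metric_ttest", "experiment_pvalues", "reproducibility_filter",
    "normalize_and_pool", "bonferroni_screen", "run_screen",
    "heatmap_matrix", "plot_heatmap", "multi_group_anova", "plant_effect",
]

BONFERRONI_M = 94


class DegenerateGroupError(ValueError):
    """A contrasted group has fewer than two usable values."""


@dataclass(frozen=True)
class ContrastSpec:
    """Which genotype groups are 'mutant' and which are 'sibling'."""

    mutant: frozenset = frozenset({"mut"})
    sibling: frozenset = frozenset({"wt", "het"})

    @classmethod
    def het_vs_wt(cls) -> "ContrastSpec":
        """Contrast used for lines with gross homozygous morphological defects."""
        return cls(mutant=frozenset({"het"}), sibling=frozenset({"wt"}))


@dataclass
class ExperimentData:
    """One behavioral run: metric matrix plus per-larva genotype labels."""

    experiment_id: str
    metrics: pd.DataFrame           # larva × metric
    genotypes: pd.Series            # larva -> genotype label
    treatment: str = "E3"

    def __post_init__(self) -> None:
        self.genotypes = self.genotypes.reindex(self.metrics.index)
        if self.genotypes.isna().any():
            raise ValueError("every larva must be genotyped")

    def group_values(self, metric: str, groups: frozenset) -> np.ndarray:
        sel = self.genotypes.isin(groups)
        return self.metrics.loc[sel, metric].dropna().to_numpy()


@dataclass
class ScreenResult:
    """Per-metric screen outcome for one mutant line."""

    line_id: str
    table: pd.DataFrame  # index metric; p_exp1, p_exp2, reproducible,
    #                      pooled_p, significant, sd_difference, excluded
    alpha: float = 0.05
    m: int = BONFERRONI_M
    single_experiment: bool = False

    @property
    def significant_metrics(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def metric_ttest(values_a, values_b) -> tuple[float, float]:
    """Two-tailed, unpaired Student's t test (pooled variance).

    Missing values must already be dropped.  Groups of fewer than two values
    raise :class:`DegenerateGroupError`.  Two identical constant groups give
    (0, 1); distinct constant groups (zero pooled variance, unequal means)
    give (±inf, 0) as the degenerate limit.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise DegenerateGroupError(
            f"need >= 2 values per group, got {len(a)} and {len(b)}")
    ma, mb = float(np.mean(a)), float(np.mean(b))
    scale = max(abs(ma), abs(mb), 1.0e-300)
    pooled_var = (((len(a) - 1) * np.var(a, ddof=1)
                   + (len(b) - 1) * np.var(b, ddof=1))
                  / (len(a) + len(b) - 2))
    if np.sqrt(pooled_var) <= 1e-9 * scale:
        # numerically constant groups: a t statistic computed from rounding
        # noise is meaningless, so resolve the degenerate limit explicitly
        if abs(ma - mb) <= 1e-9 * scale:
            return 0.0, 1.0
        return float(np.sign(ma - mb) * np.inf), 0.0
    with warnings.catch_warnings():
        # near-constant groups (e.g. frequency metrics pinned at 1) trip a
        # precision warning inside the moment calculation; the guard above
        # already handles the exactly-degenerate cases
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def multi_group_anova(groups) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA across genotype/treatment groups plus pairwise t summary.

    ``groups`` maps group label to a value array.  With two groups, F equals
    the square of the pooled t statistic.  All-identical groups give
    (0, 1, ...).
    """
    clean = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise DegenerateGroupError(f"group {name!r} has fewer than 2 values")
        clean[name] = v
    if len(clean) < 2:
        raise DegenerateGroupError("need at least two groups")
    arrays = list(clean.values())
    if all(np.var(v) == 0 for v in arrays) and len({float(np.mean(v)) for v in arrays}) == 1:
        f, p = 0.0, 1.0
    else:
        f, p = stats.f_oneway(*arrays)
        f, p = float(f), float(p)
    names = list(clean)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t, tp = metric_ttest(clean[names[i]], clean[names[j]])
            rows.append({"group_a": names[i], "group_b": names[j],
                         "t": t, "p": tp})
    return f, p, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Screen pipeline
# ---------------------------------------------------------------------------

def experiment_pvalues(
    exp: ExperimentData, contrast: ContrastSpec = ContrastSpec()
) -> pd.Series:
    """Per-metric mutant-vs-sibling p values within one experiment.

    Metrics where either group has fewer than two non-missing values get
    NaN (they cannot pass any subsequent filter).
    """
    out = {}
    for metric in exp.metrics.columns:
        a = exp.group_values(metric, contrast.mutant)
        b = exp.group_values(metric, contrast.sibling)
        try:
            _, p = metric_ttest(a, b)
        except DegenerateGroupError:
            p = np.nan
        out[metric] = p
    return pd.Series(out, name=exp.experiment_id)


def reproducibility_filter(
    pvalues_exp1: pd.Series, pvalues_exp2: pd.Series, alpha: float = 0.05
) -> set[str]:
    """Metrics with p < alpha in both independent experiments."""
    if not pvalues_exp1.index.equals(pvalues_exp2.index):
        raise ValueError("experiments use different metric registries")
    both = (pvalues_exp1 < alpha) & (pvalues_exp2 < alpha)
    return set(pvalues_exp1.index[both])


def normalize_and_pool(
    experiments: list[ExperimentData], contrast: ContrastSpec = ContrastSpec()
) -> tuple[ExperimentData, list[str]]:
    """Sibling-normalize each experiment and concatenate.

    Every metric value is divided by its experiment's mean sibling value, so
    the normalized sibling mean is 1 within each experiment block.  Metrics
    whose sibling mean is 0 (or undefined) in any experiment cannot be
    normalized and are excluded; their names are returned alongside.
    """
    excluded: set[str] = set()
    norm_blocks = []
    geno_blocks = []
    for exp in experiments:
        sib = exp.genotypes.isin(contrast.sibling)
        sib_mean = exp.metrics.loc[sib].mean(skipna=True)
        bad = sib_mean.index[(sib_mean == 0) | sib_mean.isna()]
        excluded.update(bad)
        block = exp.metrics.divide(sib_mean, axis=1)
        block.index = [f"{exp.experiment_id}:{i}" for i in block.index]
        norm_blocks.append(block)
        g = exp.genotypes.copy()
        g.index = block.index
        geno_blocks.append(g)
    pooled = pd.concat(norm_blocks)
    pooled = pooled.drop(columns=[c for c in excluded if c in pooled.columns])
    return (
        ExperimentData(
            experiment_id="+".join(e.experiment_id for e in experiments),
            metrics=pooled, genotypes=pd.concat(geno_blocks),
        ),
        sorted(excluded),
    )


def bonferroni_screen(
    pooled: ExperimentData,
    contrast: ContrastSpec = ContrastSpec(),
    alpha: float = 0.05,
    m: int = BONFERRONI_M,
) -> pd.DataFrame:
    """Pooled per-metric t tests with Bonferroni threshold alpha/m.

    Returns a frame indexed by metric with ``pooled_p``, ``pass_bonferroni``
    and ``sd_difference`` (mutant mean − sibling mean in sibling-SD units,
    computed on the pooled normalized data; NaN when the sibling SD is 0).
    """
    rows = {}
    for metric in pooled.metrics.columns:
        a = pooled.group_values(metric, contrast.mutant)
        b = pooled.group_values(metric, contrast.sibling)
        try:
            _, p = metric_ttest(a, b)
        except DegenerateGroupError:
            p = np.nan
        sd = np.std(b, ddof=1) if len(b) > 1 else np.nan
        sd_diff = ((np.mean(a) - np.mean(b)) / sd
                   if len(a) and len(b) > 1 and sd and np.isfinite(sd) and sd > 0
                   else np.nan)
        rows[metric] = {
            "pooled_p": p,
            "pass_bonferroni": bool(p < alpha / m) if np.isfinite(p) else False,
            "sd_difference": sd_diff,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def run_screen(
    exp1: ExperimentData,
    exp2: ExperimentData | None,
    line_id: str,
    contrast: ContrastSpec = ContrastSpec(),
    alpha: float = 0.05,
    m: int = BONFERRONI_M,
) -> ScreenResult:
    """The full published procedure for one mutant line.

    Two independent experiments, reproducibility filter, sibling
    normalization, pooling, Bonferroni 0.05/94.  A metric is significant iff
    it is reproducible (p < alpha in both experiments) *and* its pooled p
    beats alpha/m.  Passing ``exp2=None`` invokes the single-experiment
    exception path: the reproducibility filter is skipped and the result is
    flagged accordingly.
    """
    p1 = experiment_pvalues(exp1, contrast)
    single = exp2 is None
    if single:
        p2 = pd.Series(np.nan, index=p1.index)
        reproducible = p1 < alpha
        pooled, excluded = normalize_and_pool([exp1], contrast)
    else:
        p2 = experiment_pvalues(exp2, contrast)
        repro_set = reproducibility_filter(p1, p2, alpha)
        reproducible = p1.index.to_series().isin(repro_set)
        pooled, excluded = normalize_and_pool([exp1, exp2], contrast)
    bonf = bonferroni_screen(pooled, contrast, alpha, m)
    table = pd.DataFrame({
        "p_exp1": p1,
        "p_exp2": p2,
        "reproducible": reproducible.astype(bool),
        "excluded": p1.index.to_series().isin(excluded),
    })
    table = table.join(bonf)
    table["pass_bonferroni"] = table["pass_bonferroni"].fillna(False).astype(bool)
    table["significant"] = (
        table["reproducible"] & table["pass_bonferroni"] & ~table["excluded"])
    return ScreenResult(line_id=line_id, table=table, alpha=alpha, m=m,
                        single_experiment=single)


# ---------------------------------------------------------------------------
# Heatmaps
# ---------------------------------------------------------------------------

def heatmap_matrix(
    results: dict[str, ScreenResult] | list[ScreenResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(line × metric) signed SD-difference matrix plus significance mask.

    SD differences are in sibling-SD units on pooled normalized data
    (negative = lower in mutants); the mask marks metrics surviving the full
    reproducibility + Bonferroni procedure.
    """
    if isinstance(results, dict):
        results = list(results.values())
    if not results:
        raise ValueError("no screened lines")
    sd = pd.DataFrame({r.line_id: r.table["sd_difference"] for r in results}).T
    mask = pd.DataFrame({r.line_id: r.table["significant"] for r in results}).T
    return sd, mask.fillna(False).astype(bool)


def plot_heatmap(sd: pd.DataFrame, mask: pd.DataFrame, path=None, vlim: float = 4.0):
    """Render the screen heatmap (blue = lower in mutants, red = higher;
    Bonferroni-significant cells marked with '#')."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(8, 0.12 * sd.shape[1]), max(2, 0.5 * sd.shape[0])))
    im = ax.imshow(sd.to_numpy(), cmap="RdBu_r", vmin=-vlim, vmax=vlim,
                   aspect="auto", interpolation="nearest")
    for i in range(sd.shape[0]):
        for j in range(sd.shape[1]):
            if mask.iloc[i, j]:
                ax.text(j, i, "#", ha="center", va="center", fontsize=6)
    ax.set_yticks(range(sd.shape[0]), sd.index)
    ax.set_xticks([])
    ax.set_xlabel("behavioral metric")
    fig.colorbar(im, ax=ax, label="difference (sibling SDs)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Simulation helper
# ---------------------------------------------------------------------------

def plant_effect(
    metrics: pd.DataFrame,
    genotypes: pd.Series,
    metric: str,
    k_sd: float,
    contrast: ContrastSpec = ContrastSpec(),
) -> pd.DataFrame:
    """Shift one metric in the mutant group by ``k_sd`` sibling SDs.

    Used to plant a known effect into a simulated cohort for power and
    recovery checks.
    """
    out = metrics.copy()
    sib = genotypes.reindex(out.index).isin(contrast.sibling)
    sd = out.loc[sib, metric].std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"sibling SD for {metric!r} is degenerate")
    mut = genotypes.reindex(out.index).isin(contrast.mutant)
    out.loc[mut, metric] = out.loc[mut, metric] + k_sd * sd
    return out
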