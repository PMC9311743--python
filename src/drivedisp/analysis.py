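"""Evolved-phenotype statistics: chromosome sampling, dispersal propensities
at named densities, genotype differences with t-distribution confidence
intervals, and heatmap-table assembly for sweeps.

The unit of analysis is the chromosome, not the mouse: every chromosome of
every living mouse during the final ten turns of a coexisting run is
eligible, pooled across the replicates of a condition and subsampled to at
most 100,000 per allele class.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rules import reaction_norm
from .scenarios import SweepResult
from .simulate import RunResult

#: cap on pooled chromosomes per allele class per condition
SAMPLE_CAP = 100_000


class EmptySampleError(ValueError):
    """Raised when a condition has no coexisting replicate to sample from."""


def sample_chromosomes(results: list[RunResult], cap: int = SAMPLE_CAP,
                       rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Pool the last-ten-turn chromosome samples of the coexisting runs of
    one condition and uniformly subsample to ``cap`` per allele.

    Returns a frame with columns ``replicate, seed, turn, allele, d0, d1``;
    ``allele`` is "+" or "t". Raises :class:`EmptySampleError` if no run
    completed with both chromosome classes alive.
    """
    rng = np.random.default_rng(rng)
    frames = []
    for i, res in enumerate(results):
        if not res.completed or res.samples is None:
            continue
        f = res.samples.copy()
        f.insert(0, "seed", res.seed)
        f.insert(0, "replicate", i)
        frames.append(f)
    if not frames:
        raise EmptySampleError("no coexisting replicate to sample chromosomes from")
    pooled = pd.concat(frames, ignore_index=True)
    kept = []
    for _, group in pooled.groupby("allele", sort=True):
        if len(group) > cap:
            idx = rng.choice(len(group), size=cap, replace=False)
            group = group.iloc[np.sort(idx)]
        kept.append(group)
    return pd.concat(kept, ignore_index=True)


def propensity_at(samples: pd.DataFrame, density: float | None) -> pd.DataFrame:
    """Evaluate every sampled chromosome's reaction norm at ``density``.

    ``density=None`` gives the density-independent propensity (the raw D0),
    the natural summary for one-locus chromosomes. Adds a ``propensity``
    column (shares the simulator's clamped-linear reaction norm).
    """
    out = samples.copy()
    if density is None:
        out["propensity"] = np.clip(out["d0"].to_numpy(), 0.0, 1.0)
    else:
        out["propensity"] = reaction_norm(out["d0"].to_numpy(),
                                          out["d1"].to_numpy(), density)
    return out


@dataclass(frozen=True)
class DispersalDiffSummary:
    """Mean t-minus-+ dispersal-propensity difference with its 95% CI at a
    named density (the unit of the results heatmaps)."""

    density_label: str
    density_value: float | None
    mean_diff: float
    ci_lo: float
    ci_hi: float
    n_t: int
    n_plus: int

    @property
    def clear_difference(self) -> bool:
        """True when the CI excludes zero."""
        return self.ci_lo > 0.0 or self.ci_hi < 0.0


def diff_ci(prop_t: np.ndarray, prop_plus: np.ndarray, level: float = 0.95,
            welch: bool = False, density_label: str = "overall",
            density_value: float | None = None) -> DispersalDiffSummary:
    """Mean difference (t minus +) of two propensity samples with a
    t-distribution CI.

    The standard error is ``sqrt(var_t/n_t + var_plus/n_plus)``; the degrees
    of freedom equal the total number of chromosomes ``n_t + n_plus``
    (``welch=True`` switches to the Welch-Satterthwaite df for sensitivity
    analysis). Requires at least two observations per class.
    """
    x_t = np.asarray(prop_t, dtype=float)
    x_p = np.asarray(prop_plus, dtype=float)
    n_t, n_p = x_t.size, x_p.size
    if n_t < 2 or n_p < 2:
        raise ValueError("need >= 2 chromosomes per allele class for a variance")
    vt = x_t.var(ddof=1)
    vp = x_p.var(ddof=1)
    se = np.sqrt(vt / n_t + vp / n_p)
    mean_diff = float(x_t.mean() - x_p.mean())
    if welch:
        num = (vt / n_t + vp / n_p) ** 2
        den = (vt / n_t) ** 2 / (n_t - 1) + (vp / n_p) ** 2 / (n_p - 1)
        df = num / den if den > 0 else n_t + n_p
    else:
        df = n_t + n_p
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, df))
    half = tcrit * float(se)
    return DispersalDiffSummary(
        density_label=density_label, density_value=density_value,
        mean_diff=mean_diff, ci_lo=mean_diff - half, ci_hi=mean_diff + half,
        n_t=n_t, n_plus=n_p)


def dispersal_difference(samples: pd.DataFrame, density: float | None = None,
                         density_label: str | None = None,
                         welch: bool = False) -> DispersalDiffSummary:
    """t-minus-+ propensity difference of a pooled chromosome sample at one
    density (``None`` = density-independent / overall)."""
    if density_label is None:
        density_label = "overall" if density is None else f"density_{density:g}"
    evaluated = propensity_at(samples, density)
    prop = evaluated["propensity"].to_numpy()
    is_t = (evaluated["allele"] == "t").to_numpy()
    return diff_ci(prop[is_t], prop[~is_t], welch=welch,
                   density_label=density_label, density_value=density)


def low_high_densities(params) -> tuple[float, float]:
    """The low and high evaluation densities, mean capacity -/+ one spatial
    SD (35 and 65 under the natural condition)."""
    return params.mean_k - params.sigma_k0, params.mean_k + params.sigma_k0


def condition_summaries(samples: pd.DataFrame, params,
                        welch: bool = False) -> dict[str, DispersalDiffSummary]:
    """Overall, low-density and high-density difference summaries for one
    condition's pooled sample."""
    lo, hi = low_high_densities(params)
    return {
        "overall": dispersal_difference(samples, None, "overall", welch=welch),
        "low": dispersal_difference(samples, lo, "low", welch=welch),
        "high": dispersal_difference(samples, hi, "high", welch=welch),
    }


#: stable schema of the heatmap export
HEATMAP_COLUMNS = ["x", "y", "n_replicates", "n_coexisting", "fixated",
                   "mean_diff", "ci_lo", "ci_hi", "clear_difference",
                   "n_t", "n_plus"]


def build_heatmap(sweeps: list[SweepResult], x_param: str, y_param: str,
                  density: float | None = None, cap: int = SAMPLE_CAP,
                  rng: np.random.Generator | int | None = None,
                  welch: bool = False) -> pd.DataFrame:
    """One row per sweep cell: axis coordinates, coexistence bookkeeping and
    the t-minus-+ difference with CI at the requested density.

    Cells in which no replicate kept both chromosome classes alive are
    flagged ``fixated`` and carry no difference statistics (the white cells
    of the results heatmaps); ``clear_difference`` is true exactly when the
    95% CI excludes zero.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for sweep in sweeps:
        params = sweep.condition.params
        row: dict = {
            "x": getattr(params, x_param),
            "y": getattr(params, y_param),
            "n_replicates": len(sweep.results),
            "n_coexisting": sweep.n_coexisting,
        }
        if sweep.n_coexisting == 0:
            row.update(fixated=True, mean_diff=np.nan, ci_lo=np.nan,
                       ci_hi=np.nan, clear_difference=False, n_t=0, n_plus=0)
        else:
            samples = sample_chromosomes(sweep.results, cap=cap, rng=rng)
            s = dispersal_difference(samples, density, welch=welch)
            row.update(fixated=False, mean_diff=s.mean_diff, ci_lo=s.ci_lo,
                       ci_hi=s.ci_hi, clear_difference=s.clear_difference,
                       n_t=s.n_t, n_plus=s.n_plus)
        rows.append(row)
    return pd.DataFrame(rows, columns=HEATMAP_COLUMNS)


def positive_clear_fraction(heatmap: pd.DataFrame) -> tuple[float, int]:
    """Among cells with a clear (CI excludes 0) difference: the fraction in
    which the driver disperses more, and the number of such cells."""
    clear = heatmap[heatmap["clear_difference"]]
    n = len(clear)
    if n == 0:
        return float("nan"), 0
    return float((clear["mean_diff"] > 0).mean()), n
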