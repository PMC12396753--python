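"""Model evaluation: empirical tracks, RMSD/Pearson, cross-validation.

The empirical per-nucleotide probability of R-loop membership at position
t is the number of holdout footprints covering t divided by the holdout
size.  Predictions are scored against it with the root mean square
deviation and the Pearson correlation over all gene-region positions.
Hyperparameters (k, p) are chosen by 3-fold cross-validation on a full
training dataset, minimizing mean RMSD with mean Pearson as tie-break.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grammar import GrammarModel, ProductionRule
from .io import Dataset, PlasmidSequence
from .predict import ProbabilityTrack, ensemble_predict

logger = logging.getLogger(__name__)


@dataclass
class EmpiricalTrack:
    """Observed per-nucleotide R-loop frequency over the gene region."""

    plasmid: str
    b: int
    e: int
    values: np.ndarray
    n_rloops: int


@dataclass
class EvalReport:
    rmsd: float
    pearson_r: float
    n_positions: int
    fold: int | None = None
    k: int | None = None
    p: int | None = None


def empirical_track(holdout: Dataset, plasmid: PlasmidSequence) -> EmpiricalTrack:
    """Coverage of the holdout footprints divided by the holdout size."""
    if len(holdout) == 0:
        raise ValueError("empty holdout set")
    b, e = plasmid.gene_region
    diff = np.zeros(e - b + 2)
    for rec in holdout.records:
        diff[max(rec.i, b) - b] += 1
        diff[min(rec.j, e) - b + 1] -= 1
    cov = np.cumsum(diff[:-1]) / len(holdout)
    return EmpiricalTrack(plasmid=plasmid.name, b=b, e=e, values=cov, n_rloops=len(holdout))


def compare_tracks(pred: ProbabilityTrack, emp: EmpiricalTrack) -> EvalReport:
    """RMSD and Pearson correlation over identical position ranges.

    A constant track makes the Pearson correlation undefined; it is
    reported as NaN with a warning.
    """
    if (pred.b, pred.e) != (emp.b, emp.e):
        raise ValueError(
            f"position ranges differ: [{pred.b}, {pred.e}] vs [{emp.b}, {emp.e}]"
        )
    x, y = pred.mean, emp.values
    rmsd = float(np.sqrt(np.mean((x - y) ** 2)))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant track: Pearson correlation undefined")
        r = float("nan")
    else:
        r = float(stats.pearsonr(x, y)[0])
    return EvalReport(rmsd=rmsd, pearson_r=r, n_positions=len(x))


def kfold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition into folds whose sizes differ by at most one."""
    if n < n_folds:
        raise ValueError(f"cannot split {n} records into {n_folds} folds")
    order = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(order, n_folds)]


def threefold_cv(
    full_training: Mapping[str, Dataset],
    plasmids: Mapping[str, PlasmidSequence],
    grid: Sequence[tuple[int, int]] = ((3, 7), (3, 13), (4, 7), (4, 13), (5, 7), (5, 13)),
    n_models: int = 30,
    subsample_frac: float = 0.10,
    dict_mode: str = "stochastic",
    seed: int = 0,
    n_folds: int = 3,
    max_len: int | None = None,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Nested cross-validation over a (k, p) grid.

    Each fold reserves one third of every plasmid's full training dataset
    for validation and trains an ensemble on the rest; predictions are
    scored against the validation coverage track.  Returns the per-fold
    report table and the winning (k, p): lowest mean RMSD, ties broken by
    highest mean Pearson.  Record lengths are re-rounded to each k inside
    the loop so every candidate parameter sees correctly preprocessed
    intervals.
    """
    from .io import preprocess

    names = sorted(full_training)
    rng = np.random.default_rng(seed)
    folds = {n: kfold_indices(len(full_training[n]), n_folds, rng) for n in names}
    # common random numbers: one seed per fold, shared by every (k, p), so
    # grid comparisons are paired and not confounded by subsample draws
    fold_seeds = rng.integers(0, 2**31 - 1, size=n_folds)
    rows = []
    for gidx, (k, p) in enumerate(grid):
        for fold in range(n_folds):
            train: dict[str, Dataset] = {}
            valid: dict[str, Dataset] = {}
            for n in names:
                ds = full_training[n]
                vidx = set(folds[n][fold].tolist())
                tr = [ds.records[t] for t in range(len(ds)) if t not in vidx]
                va = [ds.records[t] for t in range(len(ds)) if t in vidx]
                train[n] = preprocess(
                    Dataset(tr, ds.plasmid, ds.topology), plasmids[n], k
                )
                valid[n] = Dataset(va, ds.plasmid, ds.topology, provenance="validation")
            tracks = ensemble_predict(
                train, plasmids, k, p,
                n_models=n_models, subsample_frac=subsample_frac,
                dict_mode=dict_mode,
                seed=int(fold_seeds[fold]),
                max_len=max_len,
            )
            for n in names:
                rep = compare_tracks(tracks[n], empirical_track(valid[n], plasmids[n]))
                rows.append(
                    {"k": k, "p": p, "fold": fold, "plasmid": n,
                     "rmsd": rep.rmsd, "pearson_r": rep.pearson_r}
                )
    report = pd.DataFrame(rows)
    summary = report.groupby(["k", "p"])[["rmsd", "pearson_r"]].mean()
    best = summary.sort_values(["rmsd", "pearson_r"], ascending=[True, False]).index[0]
    return report, (int(best[0]), int(best[1]))


#: the six rules highlighted when comparing topologies
MAIN_RULES = (
    ProductionRule("S", "sig", False),
    ProductionRule("S", "sigH", False),
    ProductionRule("R", "tau", False),
    ProductionRule("R", "tauH", False),
    ProductionRule("Q", "sig", False),
    ProductionRule("Q", "sigH", False),
)


def rule_probability_report(
    models_by_topology: Mapping[str, Sequence[GrammarModel]],
    rules: Sequence[ProductionRule] = MAIN_RULES,
    with_tests: bool = True,
) -> pd.DataFrame:
    """Distribution summary of rule probabilities per topology.

    Reports median, quartiles and 1.5*IQR whiskers per (topology, rule)
    over an ensemble, plus (optionally) pairwise two-sample t-tests across
    topologies with Bonferroni adjustment.
    """
    rows = []
    for topo, models in models_by_topology.items():
        if not models:
            raise ValueError(f"no models for topology {topo}")
        for rule in rules:
            vals = np.array([m.prob(rule) for m in models])
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            in_lo = vals[vals >= q1 - 1.5 * iqr]
            in_hi = vals[vals <= q3 + 1.5 * iqr]
            rows.append(
                {"topology": topo, "rule": str(rule), "median": med,
                 "q1": q1, "q3": q3,
                 "whisker_lo": in_lo.min() if in_lo.size else q1,
                 "whisker_hi": in_hi.max() if in_hi.size else q3,
                 "n_models": len(models)}
            )
    report = pd.DataFrame(rows)
    if not with_tests:
        return report
    topos = sorted(models_by_topology)
    tests = []
    pairs = list(itertools.combinations(topos, 2))
    n_tests = len(pairs) * len(rules)
    for rule in rules:
        for a, b in pairs:
            va = np.array([m.prob(rule) for m in models_by_topology[a]])
            vb = np.array([m.prob(rule) for m in models_by_topology[b]])
            if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
                pval = 1.0
            else:
                pval = float(stats.ttest_ind(va, vb).pvalue)
                if math.isnan(pval):
                    pval = 1.0
            tests.append(
                {"rule": str(rule), "topology_a": a, "topology_b": b,
                 "p_value": pval,
                 "p_adjusted": min(1.0, pval * n_tests)}
            )
    report.attrs["pairwise_tests"] = pd.DataFrame(tests)
    return report
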