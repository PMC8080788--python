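"""Per-sample activity scoring: orchestrate enrichment over all samples and
motifs into a samples × miRNAs activity matrix, plus downstream utilities
(activity–expression correlation, cell-type specificity, method comparison).

The activity score is −log10(p) · sign(statistic): positive scores mean the
miRNA's target motif is enriched among that sample's repressed genes, read as
high miRNA activity in that sample/cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from . import enrichment
from ._io import PathLike, open_text
from .enrichment import P_FLOOR
from .motif_probability import MotifProbabilityTable
from .utr_sequences import UtrRecord

log = logging.getLogger(__name__)

METHODS = ("mrs", "bb", "hypergeom", "tarbase")

MAX_SCORE = -np.log10(P_FLOOR)  # 300: the p-value floor before log transform


def score_from_pvalue(p: float, direction: int) -> float:
    """Activity score −log10(max(p, 1e−300)) · direction for p in (0, 1]."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p-value {p} outside (0, 1]")
    if direction not in (-1, 1):
        raise ValueError(f"direction must be -1 or +1, got {direction}")
    return float(-np.log10(max(p, P_FLOOR)) * direction)


@dataclass
class ActivityMatrix:
    """Samples × miRNAs activity scores with provenance metadata."""

    scores: pd.DataFrame  # index sample ids, columns miRNA names
    method: str
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path: PathLike) -> None:
        with open_text(path, "wt") as fh:
            fh.write(f"# method={self.method}\n")
            for key in sorted(self.metadata):
                fh.write(f"# {key}={self.metadata[key]}\n")
            self.scores.to_csv(fh, sep="\t", index_label="sample_id")


def _indicator_matrix(
    genes: Sequence[str], utrs: Mapping[str, UtrRecord], motifs: Sequence[str]
) -> np.ndarray:
    """Boolean genes × motifs presence matrix via substring search."""
    mat = np.zeros((len(genes), len(motifs)), dtype=bool)
    for j, motif in enumerate(motifs):
        for i, g in enumerate(genes):
            if motif in utrs[g].sequence:
                mat[i, j] = True
    return mat


def _motif_scores_one_sample(
    fc_col: pd.Series,
    I: np.ndarray,
    P: np.ndarray,
    method: str,
    cutoff_grid: Optional[Sequence[int]],
) -> np.ndarray:
    """Scores for every motif column in one sample. Motifs without contrast
    (present in all or no genes) score 0 — no evidence either way."""
    n, m = I.shape
    scores = np.zeros(m)
    contrast = (I.sum(axis=0) > 0) & (I.sum(axis=0) < n)

    if method == "mrs":
        # vectorised across motifs: T = c @ (I - P), Var = c^2 @ P(1-P)
        r = stats.rankdata(fc_col.to_numpy(dtype=float), method="average")
        c = (n + 1) / 2.0 - r
        T = c @ (I - P)
        var = (c * c) @ (P * (1.0 - P))
        ok = contrast & (var > 0)
        z = np.zeros(m)
        z[ok] = T[ok] / np.sqrt(var[ok])
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)
        sign = np.where(z >= 0, 1.0, -1.0)
        scores[ok] = (-np.log10(p) * sign)[ok]
        return scores

    # walk-based methods use the stable full ordering
    order = _ordering_indices(fc_col)
    I_ord = I[order]
    P_ord = P[order]

    if method == "bb":
        V = (P * (1.0 - P)).sum(axis=0)
        ok = contrast & (V > 0)
        s = np.cumsum(I_ord - P_ord, axis=0)
        k = np.arange(1, n + 1)[:, None]
        bridge = (s - (k / n) * s[-1]) / np.sqrt(np.where(V > 0, V, 1.0))
        imax = np.argmax(np.abs(bridge), axis=0)
        b_at = bridge[imax, np.arange(m)]
        d = np.abs(b_at) + enrichment.BGK_BETA / np.sqrt(n)
        p = np.array([enrichment.kolmogorov_sup_pvalue(float(x)) for x in d])
        direction = np.where(b_at >= 0, 1.0, -1.0)
        scores[ok] = (-np.log10(np.clip(p, P_FLOOR, 1.0)) * direction)[ok]
        return scores

    if method == "hypergeom":
        grid = (
            enrichment.default_cutoff_grid(n)
            if cutoff_grid is None
            else np.asarray(cutoff_grid, dtype=int)
        )
        K = I.sum(axis=0)
        cum = np.cumsum(I_ord, axis=0)[grid - 1]  # cutoffs × motifs
        p_over = stats.hypergeom.sf(cum - 1, n, K[None, :], grid[:, None])
        p_under = stats.hypergeom.cdf(cum, n, K[None, :], grid[:, None])
        po = p_over.min(axis=0)
        pu = p_under.min(axis=0)
        direction = np.where(po <= pu, 1.0, -1.0)
        p = np.clip(np.minimum(po, pu), P_FLOOR, 1.0)
        scores[contrast] = (-np.log10(p) * direction)[contrast]
        return scores

    raise ValueError(f"unknown method {method!r}")


def _ordering_indices(fc_col: pd.Series) -> np.ndarray:
    genes = fc_col.index.to_numpy(dtype=object)
    values = fc_col.to_numpy(dtype=float)
    return np.lexsort((genes, values))


def compute_activity(
    fold_change: pd.DataFrame,
    utrs: Mapping[str, UtrRecord],
    motif_map: Mapping[str, Sequence[str]],
    prob_table: Optional[MotifProbabilityTable] = None,
    method: str = "mrs",
    targets: Optional[Mapping[str, set]] = None,
    cutoff_grid: Optional[Sequence[int]] = None,
    n_jobs: int = 1,
) -> ActivityMatrix:
    """Run the chosen enrichment statistic per sample and assemble activities.

    The gene universe is the intersection of expression genes and UTR-bearing
    genes (genes lacking a UTR are excluded from ranking, not scored as
    motif-absent).  Scores are computed once per unique target motif and
    broadcast to all miRNAs sharing it.  Samples are independent work units;
    results are identical for any ``n_jobs``.

    ``method="tarbase"`` ignores motifs/probabilities and instead rank-sum
    tests each miRNA's curated target set (``targets``: name → gene set)
    against the rest of the expression genes found in the target lists.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")

    if method == "tarbase":
        if not targets:
            raise ValueError("tarbase method requires a target mapping")
        return _compute_activity_targets(fold_change, targets, n_jobs)

    if prob_table is None:
        raise ValueError(f"method {method!r} requires a motif probability table")
    genes = [g for g in fold_change.index if g in utrs]
    if not genes:
        raise ValueError("no overlap between expression genes and UTR genes")
    motifs = sorted(motif_map)
    fc = fold_change.loc[genes]
    I = _indicator_matrix(genes, utrs, motifs).astype(float)
    P = prob_table.probs.loc[genes, motifs].to_numpy(dtype=float)
    P = np.clip(P, 0.0, np.nextafter(1.0, 0.0))

    samples = list(fc.columns)
    rows = Parallel(n_jobs=n_jobs, prefer="threads")(
        delayed(_motif_scores_one_sample)(fc[s], I, P, method, cutoff_grid)
        for s in samples
    )
    motif_scores = pd.DataFrame(np.vstack(rows), index=samples, columns=motifs)

    mirna_names = sorted({name for names in motif_map.values() for name in names})
    data = {name: motif_scores[m] for m, names in motif_map.items() for name in names}
    scores = pd.DataFrame(data, index=motif_scores.index)[mirna_names]
    return ActivityMatrix(
        scores=scores,
        method=method,
        metadata={
            "gene_count": len(genes),
            "motif_count": len(motifs),
            "utr_checksum": prob_table.utr_checksum,
        },
    )


def _compute_activity_targets(
    fold_change: pd.DataFrame, targets: Mapping[str, set], n_jobs: int
) -> ActivityMatrix:
    universe = [g for g in fold_change.index
                if any(g in tset for tset in targets.values())]
    if not universe:
        raise ValueError("no overlap between expression genes and target-list genes")
    fc = fold_change.loc[universe]
    mirnas = sorted(targets)
    masks = {m: np.fromiter((g in targets[m] for g in universe), bool, len(universe))
             for m in mirnas}

    def one_sample(col: pd.Series) -> np.ndarray:
        values = col.to_numpy(dtype=float)
        out = np.zeros(len(mirnas))
        for j, m in enumerate(mirnas):
            mask = masks[m]
            if not mask.any():
                raise ValueError(f"target set for {m!r} does not intersect ranked genes")
            if mask.all():
                out[j] = 0.0
                continue
            res = enrichment.targetset_ranksum(values, mask)
            out[j] = score_from_pvalue(res.p_value, res.direction)
        return out

    rows = Parallel(n_jobs=n_jobs, prefer="threads")(
        delayed(one_sample)(fc[s]) for s in fc.columns
    )
    scores = pd.DataFrame(np.vstack(rows), index=list(fc.columns), columns=mirnas)
    return ActivityMatrix(
        scores=scores,
        method="tarbase",
        metadata={"gene_count": len(universe), "mirna_count": len(mirnas)},
    )


def activity_expression_correlation(
    activity: Sequence[float],
    expression: Sequence[float],
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlate an activity vector with a matched expression vector.

    Returns (r, two-sided p).  Non-finite pairs are dropped; a constant
    vector yields (nan, nan) with a warning.
    """
    a = np.asarray(activity, dtype=float)
    e = np.asarray(expression, dtype=float)
    if a.shape != e.shape:
        raise ValueError("activity and expression vectors must have equal length")
    mask = np.isfinite(a) & np.isfinite(e)
    if mask.sum() < 3:
        raise ValueError("need at least 3 finite pairs")
    a, e = a[mask], e[mask]
    if np.ptp(a) == 0 or np.ptp(e) == 0:
        warnings.warn("constant vector: correlation undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    if method == "pearson":
        r, p = stats.pearsonr(a, e)
    elif method == "spearman":
        r, p = stats.spearmanr(a, e)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def celltype_specificity(
    activity: ActivityMatrix,
    cell_labels: pd.Series,
    min_cells: int = 5,
    threshold: float = 3.0,
) -> pd.DataFrame:
    """Score each (miRNA, cell type) for outlying activity.

    robust_z = (median of type − global median) / (1.4826 × global MAD);
    rows with |robust_z| >= threshold are flagged.  Cell types with fewer
    than ``min_cells`` cells are ignored; miRNAs with zero global MAD are
    skipped with a warning.
    """
    labels = cell_labels.reindex(activity.scores.index)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValueError(f"cells without labels: {missing[:5]}")
    counts = labels.value_counts()
    types = sorted(counts.index[counts >= min_cells])
    if len(types) < 2:
        raise ValueError(f"need >=2 cell types with >= {min_cells} cells, got {len(types)}")

    rows = []
    for mirna in activity.scores.columns:
        col = activity.scores[mirna]
        global_median = float(col.median())
        mad = float(stats.median_abs_deviation(col, scale=1.0))
        if mad == 0.0:
            warnings.warn(f"{mirna}: zero MAD, specificity undefined; skipped", stacklevel=2)
            continue
        for ct in types:
            z = (float(col[labels == ct].median()) - global_median) / (1.4826 * mad)
            rows.append({
                "mirna": mirna,
                "cell_type": ct,
                "robust_z": z,
                "flagged": abs(z) >= threshold,
            })
    return pd.DataFrame(rows, columns=["mirna", "cell_type", "robust_z", "flagged"])


def method_correlation_report(
    activities: Mapping[str, ActivityMatrix],
    mirna_expression: pd.DataFrame,
    corr_method: str = "pearson",
) -> pd.DataFrame:
    """Per-miRNA activity–expression correlation for each scoring method.

    ``mirna_expression`` is miRNAs × samples.  Returns a tidy frame with one
    row per (miRNA, method) plus the max correlation across methods, sorted
    by that maximum — the comparison view for choosing a default statistic
    on datasets with matched miRNA expression.
    """
    records: dict[str, dict[str, float]] = {}
    for method, act in activities.items():
        common = [m for m in act.scores.columns if m in mirna_expression.index]
        for mirna in common:
            expr = mirna_expression.loc[mirna, act.scores.index].to_numpy(dtype=float)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, _ = activity_expression_correlation(
                        act.scores[mirna].to_numpy(), expr, corr_method
                    )
            except ValueError:
                r = float("nan")
            records.setdefault(mirna, {})[method] = r
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "mirna"
    df["max_correlation"] = df.max(axis=1)
    return df.sort_values("max_correlation", ascending=False)


def read_target_tsv(path: PathLike) -> dict[str, set]:
    """Read a two-column (mirna_name, gene_id) TSV into name → gene set."""
    targets: dict[str, set] = {}
    with open_text(path) as fh:
        first = True
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            mirna, gene = line.split("\t")[:2]
            if first and (mirna.lower() in ("mirna", "mirna_name")):
                first = False
                continue
            first = False
            targets.setdefault(mirna, set()).add(gene)
    return targets
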