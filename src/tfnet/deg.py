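"""Relative expression, noise-based differential-expression calling and
DEG set summaries.

The differential-expression probability is a deliberately simplified
analogue of noise-distribution methods: for each gene the signal pair
``(M, D)`` — absolute log2 ratio and absolute difference of condition
means — is compared against a pooled noise cloud built from every
within-condition replicate pair across all genes, and the probability is
the fraction of noise points strictly dominated in both coordinates.
It is monotone in (M, D) and lands in [0, 1]; it is NOT the published
NOIseq estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kendalltau

logger = logging.getLogger(__name__)

DEFAULT_PROB_THRESHOLD = 0.6
DEFAULT_LOG2FC_THRESHOLD = 1.0
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class ExpressionMatrix:
    """FPKM values (genes x samples) plus sample metadata.

    ``metadata`` is indexed by sample id with columns ``condition`` and
    ``replicate``; exactly one condition must equal ``control``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    control: str = "control"

    def __post_init__(self) -> None:
        self.values.index.name = "gene_id"
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("non-numeric expression values")
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite FPKM at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative FPKM at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        conditions = set(self.metadata["condition"])
        if self.control not in conditions:
            raise ValueError(f"no samples labeled control ({self.control!r})")

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.metadata["condition"]))

    @property
    def treatments(self) -> list[str]:
        return [c for c in self.conditions if c != self.control]

    def samples_for(self, condition: str) -> list[str]:
        sel = self.metadata.index[self.metadata["condition"] == condition]
        cols = [s for s in self.values.columns if s in set(sel)]
        if not cols:
            raise ValueError(f"condition {condition!r} has zero replicates")
        return cols

    def condition_means(self) -> pd.DataFrame:
        """Mean FPKM per gene per condition."""
        return pd.DataFrame(
            {c: self.values[self.samples_for(c)].mean(axis=1)
             for c in self.conditions}
        )


@dataclass
class RelativeExpression:
    """log2 fold-change matrix (genes x treatments) vs the control."""

    values: pd.DataFrame
    pseudocount: float


@dataclass(frozen=True)
class DegCall:
    gene_id: str
    treatment: str
    probability: float
    log2fc: float
    is_deg: bool
    is_crucial: bool = False

    @property
    def direction(self) -> str:
        if self.log2fc > 0:
            return "up"
        if self.log2fc < 0:
            return "down"
        return "none"


def relative_expression(
    matrix: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> RelativeExpression:
    """log2((mean treatment FPKM + c) / (mean control FPKM + c))."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    means = matrix.condition_means()
    ctrl = means[matrix.control] + pseudocount
    rel = pd.DataFrame(
        {
            t: np.log2((means[t] + pseudocount) / ctrl)
            for t in matrix.treatments
        }
    )
    return RelativeExpression(rel, pseudocount)


# ---------------------------------------------------------------------------
# noise-based probability


def _noise_points(
    matrix: ExpressionMatrix, pseudocount: float
) -> np.ndarray:
    """Pooled (M, D) noise cloud from all within-condition replicate pairs."""
    points = []
    for cond in matrix.conditions:
        cols = matrix.samples_for(cond)
        if len(cols) < 2:
            continue
        x = matrix.values[cols].to_numpy(dtype=float)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                a, b = x[:, i], x[:, j]
                m = np.abs(np.log2((a + pseudocount) / (b + pseudocount)))
                d = np.abs(a - b)
                points.append(np.column_stack([m, d]))
    if not points:
        raise ValueError(
            "no condition has >=2 replicates: noise distribution undefined"
        )
    return np.vstack(points)


def noise_probability(
    matrix: ExpressionMatrix,
    treatment: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    noise: np.ndarray | None = None,
) -> pd.Series:
    """Per-gene probability that (M, D) strictly dominates the noise.

    ``noise`` allows reusing a precomputed pooled cloud across
    treatments (it only depends on replicates, not on the contrast).
    """
    if treatment not in matrix.treatments:
        raise ValueError(f"unknown treatment {treatment!r}")
    if noise is None:
        noise = _noise_points(matrix, pseudocount)
    means = matrix.condition_means()
    t = means[treatment].to_numpy(dtype=float)
    c = means[matrix.control].to_numpy(dtype=float)
    m_sig = np.abs(np.log2((t + pseudocount) / (c + pseudocount)))
    d_sig = np.abs(t - c)

    n_noise = noise.shape[0]
    probs = np.empty(len(m_sig))
    chunk = max(1, int(2e7) // max(n_noise, 1))
    for lo in range(0, len(m_sig), chunk):
        hi = min(lo + chunk, len(m_sig))
        dominated = (noise[None, :, 0] < m_sig[lo:hi, None]) & (
            noise[None, :, 1] < d_sig[lo:hi, None]
        )
        probs[lo:hi] = dominated.sum(axis=1) / n_noise
    return pd.Series(probs, index=matrix.values.index, name=treatment)


def noise_probabilities(
    matrix: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Probability matrix (genes x treatments) sharing one noise cloud."""
    noise = _noise_points(matrix, pseudocount)
    return pd.DataFrame(
        {
            t: noise_probability(matrix, t, pseudocount, noise)
            for t in matrix.treatments
        }
    )


def call_degs(
    rel: RelativeExpression,
    probs: pd.DataFrame,
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
    log2fc_threshold: float = DEFAULT_LOG2FC_THRESHOLD,
    fc_inclusive: bool = True,
) -> list[DegCall]:
    """Flag DEGs: probability >= prob_threshold AND |log2FC| >= threshold.

    ``fc_inclusive=False`` switches the fold-change comparison to strict
    ``>`` (some descriptions use "greater than 1").
    """
    calls: list[DegCall] = []
    for t in rel.values.columns:
        for gene in rel.values.index:
            fc = float(rel.values.at[gene, t])
            p = float(probs.at[gene, t])
            if fc_inclusive:
                passes_fc = abs(fc) >= log2fc_threshold
            else:
                passes_fc = abs(fc) > log2fc_threshold
            calls.append(
                DegCall(gene, t, p, fc, bool(p >= prob_threshold and passes_fc))
            )
    return calls


def calls_frame(calls: Iterable[DegCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "treatment": c.treatment,
                "probability": c.probability,
                "log2fc": c.log2fc,
                "direction": c.direction,
                "is_deg": c.is_deg,
                "is_crucial": c.is_crucial,
            }
            for c in calls
        ]
    )


def threshold_sweep(
    rel: RelativeExpression,
    probs: pd.DataFrame,
    prob_grid: Sequence[float] = (0.6, 0.7, 0.8, 0.9, 0.95),
    log2fc_threshold: float = DEFAULT_LOG2FC_THRESHOLD,
) -> pd.DataFrame:
    """Up/down DEG counts per treatment over a probability grid."""
    rows = []
    for p0 in prob_grid:
        calls = call_degs(rel, probs, p0, log2fc_threshold)
        for t in rel.values.columns:
            up = sum(1 for c in calls if c.treatment == t and c.is_deg and c.log2fc > 0)
            down = sum(1 for c in calls if c.treatment == t and c.is_deg and c.log2fc < 0)
            rows.append({"prob_threshold": p0, "treatment": t, "up": up, "down": down})
    return pd.DataFrame(rows)


def deg_sets(calls: Iterable[DegCall]) -> dict[str, set[str]]:
    """treatment -> set of DEG gene ids."""
    out: dict[str, set[str]] = {}
    for c in calls:
        out.setdefault(c.treatment, set())
        if c.is_deg:
            out[c.treatment].add(c.gene_id)
    return out


def venn_summary(
    calls: Iterable[DegCall],
    families: Mapping[str, str] | None = None,
) -> dict:
    """Membership-class counts over all non-empty treatment combinations.

    Returns the 2^T - 1 class counts (keyed by sorted treatment tuples),
    the number of genes that are a DEG under at least one treatment,
    and — when ``families`` maps gene -> family — the per-family totals.
    """
    sets = deg_sets(calls)
    treatments = sorted(sets)
    membership: dict[str, set[str]] = {}
    for t in treatments:
        for g in sets[t]:
            membership.setdefault(g, set()).add(t)
    class_counts: dict[tuple[str, ...], int] = {}
    for g, ts in membership.items():
        key = tuple(sorted(ts))
        class_counts[key] = class_counts.get(key, 0) + 1
    unique_total = len(membership)
    per_family: dict[str, int] = {}
    if families is not None:
        for g in membership:
            fam = families.get(g, "")
            per_family[fam] = per_family.get(fam, 0) + 1
    return {
        "treatments": treatments,
        "class_counts": class_counts,
        "unique_deg_total": unique_total,
        "unique_deg_per_family": per_family,
    }


def select_crucial(
    calls: Sequence[DegCall],
    annotations: Mapping[str, set[str]],
    crucial_terms: Sequence[str],
) -> list[DegCall]:
    """Flag DEGs annotated with >=1 configured stimulus-response term.

    ``crucial_terms`` entries match an annotation either exactly (term
    IDs) or as a case-insensitive substring (keywords).  An empty list
    is an error: silently passing every DEG through is forbidden.
    """
    if not crucial_terms:
        raise ValueError("crucial_terms must not be empty")
    exact = set(crucial_terms)
    keywords = [t.lower() for t in crucial_terms]

    def is_crucial_gene(gene: str) -> bool:
        terms = annotations.get(gene, set())
        for term in terms:
            if term in exact:
                return True
            tl = term.lower()
            if any(k in tl for k in keywords):
                return True
        return False

    flagged = {g for g in {c.gene_id for c in calls} if is_crucial_gene(g)}
    return [
        DegCall(
            c.gene_id, c.treatment, c.probability, c.log2fc, c.is_deg,
            is_crucial=bool(c.is_deg and c.gene_id in flagged),
        )
        for c in calls
    ]


def crucial_counts(
    calls: Iterable[DegCall], families: Mapping[str, str] | None = None
) -> dict:
    """Per-treatment (and per-family) distinct crucial-DEG counts."""
    per_treatment: dict[str, set[str]] = {}
    per_family_treatment: dict[tuple[str, str], set[str]] = {}
    all_crucial: set[str] = set()
    for c in calls:
        if not c.is_crucial:
            continue
        per_treatment.setdefault(c.treatment, set()).add(c.gene_id)
        all_crucial.add(c.gene_id)
        if families is not None:
            fam = families.get(c.gene_id, "")
            per_family_treatment.setdefault((fam, c.treatment), set()).add(c.gene_id)
    out = {
        "per_treatment": {t: len(s) for t, s in sorted(per_treatment.items())},
        "total": len(all_crucial),
    }
    if families is not None:
        out["per_family_treatment"] = {
            f"{fam}|{t}": len(s)
            for (fam, t), s in sorted(per_family_treatment.items())
        }
        per_family: dict[str, set[str]] = {}
        for c in calls:
            if c.is_crucial:
                per_family.setdefault(families.get(c.gene_id, ""), set()).add(
                    c.gene_id
                )
        out["per_family"] = {f: len(s) for f, s in sorted(per_family.items())}
    return out


def ddct(delta_ct: float) -> float:
    """qRT-PCR relative level: 2 ** (-delta Ct)."""
    if not np.isfinite(delta_ct):
        raise ValueError("delta_ct must be finite")
    return float(2.0 ** (-delta_ct))


# ---------------------------------------------------------------------------
# clustering of relative-expression profiles


def _kendall_distance_matrix(x: np.ndarray) -> np.ndarray:
    """1 - Kendall tau between columns; constant columns get distance 1."""
    n = x.shape[1]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if np.ptp(x[:, i]) == 0 or np.ptp(x[:, j]) == 0:
                logger.warning("constant column in tau distance; using 1")
                d = 1.0
            else:
                tau = kendalltau(x[:, i], x[:, j]).statistic
                d = 1.0 - (0.0 if np.isnan(tau) else tau)
            dist[i, j] = dist[j, i] = d
    return dist


def cluster_expression(rel: RelativeExpression) -> dict:
    """Average-linkage clustering: genes by Euclidean distance,
    treatments by 1 - Kendall tau.

    Returns linkage matrices and deterministic leaf orders (row/column
    labels are pre-sorted so ties merge stably).
    """
    vals = rel.values.sort_index()
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("need >=2 genes and >=2 treatments")
    gene_link = hierarchy.linkage(
        pdist(vals.to_numpy(), metric="euclidean"), method="average"
    )
    gene_order = [str(vals.index[i]) for i in hierarchy.leaves_list(gene_link)]
    tcols = sorted(vals.columns)
    tdist = _kendall_distance_matrix(vals[tcols].to_numpy())
    t_link = hierarchy.linkage(squareform(tdist, checks=False), method="average")
    t_order = [str(tcols[i]) for i in hierarchy.leaves_list(t_link)]
    return {
        "gene_linkage": gene_link,
        "gene_order": gene_order,
        "treatment_linkage": t_link,
        "treatment_order": t_order,
    }
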