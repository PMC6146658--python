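"""Rule-based transcription-factor family/subfamily assignment and
chromosome-distribution statistics.

Families are called from domain-hit tables only; no sequence scanning
happens here.  The rules:

* AP2/EREBP — at least one AP2 domain.  Two AP2 repeats -> subfamily
  ``AP2``; one AP2 plus a B3 domain -> ``RAV``; a single AP2 ->
  ``EREBP-unresolved`` (DREB-vs-ERF resolution needs phylogeny and is
  consumed as an optional annotation).
* bZIP — a bZIP_1 or bZIP_2 domain; subfamilies are annotation
  pass-through.
* MYB — MYB repeats; 1/2/3/4 repeats -> ``1R``/``R2R3``/``3R``/``4R``.
* NAC — a NAM domain; subfamilies are annotation pass-through.
* WRKY — a WRKY domain whose core is the canonical ``WRKYGQK`` heptad or
  an accepted degenerate (WRRY/WSKY/WKRY/WVKY/WKKY/WKNY core), AND a
  zinc-finger hit.  Two WRKY + C2H2 -> group I; one WRKY + C2H2 -> II;
  one WRKY + C2HC -> III.  A WRKY domain without a zinc finger is
  rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_CUTOFF = 1e-5

#: signature domain -> family
SIGNATURE_DOMAINS = {
    "AP2": "AP2/EREBP",
    "bZIP_1": "bZIP",
    "bZIP_2": "bZIP",
    "MYB": "MYB",
    "NAM": "NAC",
    "WRKY": "WRKY",
}

#: degenerate heptad cores still accepted as WRKY domain matches
ACCEPTED_WRKY_CORES = frozenset(
    {"WRKY", "WRRY", "WSKY", "WKRY", "WVKY", "WKKY", "WKNY"}
)

FAMILIES = ("AP2/EREBP", "bZIP", "MYB", "NAC", "WRKY")


@dataclass(frozen=True)
class DomainHit:
    """One domain match for a gene's protein product."""

    gene_id: str
    domain_name: str
    start: int
    end: int
    e_value: float
    variant: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}/{self.domain_name}: start {self.start} > end {self.end}"
            )
        if self.e_value < 0:
            raise ValueError(f"{self.gene_id}: negative E-value {self.e_value}")


@dataclass(frozen=True)
class FamilyCall:
    gene_id: str
    family: str  # one of FAMILIES or "none"
    subfamily: str = ""
    rejection_reason: str = ""

    def __post_init__(self) -> None:
        if (self.family == "none") != bool(self.rejection_reason):
            raise ValueError(
                "family='none' iff rejection_reason is set "
                f"(got family={self.family!r}, reason={self.rejection_reason!r})"
            )


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its placement and family labels."""

    gene_id: str
    species: str
    family: str = ""
    subfamily: str = ""
    chromosome: str = ""  # empty => unanchored scaffold
    sub_genome: str = ""  # A | C | unplaced
    anchored: bool = True


def _wrky_core(variant: str) -> str | None:
    """Accepted 4-letter WRKY core from a variant string, or None."""
    v = variant.strip().upper()
    for core in ACCEPTED_WRKY_CORES:
        if v.startswith(core):
            return core
    return None


def _qualifying(hits: Iterable[DomainHit], cutoff: float) -> list[DomainHit]:
    return [h for h in hits if h.e_value < cutoff]


def classify_family(
    hits: Sequence[DomainHit],
    e_value_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> FamilyCall:
    """Assign a TF family to one gene from its domain hits.

    ``hits`` must all belong to the same gene.  Hit order is irrelevant.
    """
    if not hits:
        raise ValueError("classify_family needs the gene_id; pass >=1 hit "
                         "or use classify_gene with an explicit id")
    gene_id = hits[0].gene_id
    if any(h.gene_id != gene_id for h in hits):
        raise ValueError("hits span multiple genes; group by gene first")
    return classify_gene(gene_id, hits, e_value_cutoff)


def classify_gene(
    gene_id: str,
    hits: Sequence[DomainHit],
    e_value_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> FamilyCall:
    """Family call for ``gene_id`` given its (possibly empty) hit list."""
    good = _qualifying(hits, e_value_cutoff)
    families = set()
    for h in good:
        if h.domain_name == "WRKY":
            if _wrky_core(h.variant or "WRKY") is not None:
                families.add("WRKY")
        elif h.domain_name in SIGNATURE_DOMAINS:
            families.add(SIGNATURE_DOMAINS[h.domain_name])
    if not families:
        return FamilyCall(gene_id, "none", rejection_reason="no qualifying domains")
    if len(families) > 1:
        logger.warning("%s: ambiguous signature domains %s", gene_id, sorted(families))
        return FamilyCall(gene_id, "none", rejection_reason="ambiguous")
    family = families.pop()
    if family == "WRKY":
        zf = [h for h in good if h.domain_name == "zinc_finger"]
        if not zf:
            return FamilyCall(
                gene_id, "none", rejection_reason="missing zinc finger"
            )
    return FamilyCall(gene_id, family)


def classify_subfamily(
    call: FamilyCall,
    hits: Sequence[DomainHit],
    e_value_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    annotations: Mapping[str, str] | None = None,
) -> FamilyCall:
    """Fill the subfamily field of a resolved family call.

    ``annotations`` maps gene_id -> externally supplied subfamily label
    (phylogeny-derived labels such as DREB A1..A6 or WRKY IIa..IIe); used
    for bZIP/NAC always and for AP2/EREBP singles when present.
    """
    if call.family == "none":
        raise ValueError("cannot assign a subfamily to a rejected gene")
    good = _qualifying(hits, e_value_cutoff)
    counts: dict[str, int] = {}
    for h in good:
        name = h.domain_name
        if name == "WRKY" and _wrky_core(h.variant or "WRKY") is None:
            continue
        counts[name] = counts.get(name, 0) + 1
    anno = (annotations or {}).get(call.gene_id, "")

    if call.family == "AP2/EREBP":
        n_ap2 = counts.get("AP2", 0)
        if n_ap2 == 2 and not counts.get("B3"):
            sub = "AP2"
        elif n_ap2 == 1 and counts.get("B3"):
            sub = "RAV"
        elif n_ap2 == 1:
            sub = anno or "EREBP-unresolved"
        else:
            logger.warning("%s: %d AP2 domains, unresolved", call.gene_id, n_ap2)
            sub = "unresolved"
    elif call.family == "WRKY":
        n_wrky = counts.get("WRKY", 0)
        zf_types = {
            (h.variant or "").upper()
            for h in good
            if h.domain_name == "zinc_finger"
        }
        if n_wrky == 2 and "C2H2" in zf_types:
            sub = "I"
        elif n_wrky == 1 and "C2H2" in zf_types:
            sub = anno or "II"
        elif n_wrky == 1 and "C2HC" in zf_types:
            sub = "III"
        else:
            logger.warning(
                "%s: inconsistent WRKY architecture (%d domains, zf=%s)",
                call.gene_id, n_wrky, sorted(zf_types),
            )
            sub = "unresolved"
    elif call.family == "MYB":
        n = counts.get("MYB", 0)
        sub = {1: "1R", 2: "R2R3", 3: "3R", 4: "4R"}.get(n, "unresolved")
        if sub == "unresolved":
            logger.warning("%s: %d MYB repeats, unresolved", call.gene_id, n)
    else:  # bZIP / NAC: annotation pass-through
        sub = anno
    return replace(call, subfamily=sub)


def classify_table(
    hits_by_gene: Mapping[str, Sequence[DomainHit]],
    e_value_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    annotations: Mapping[str, str] | None = None,
) -> list[FamilyCall]:
    """Classify every gene; one call (accepted or rejected) per gene."""
    calls = []
    for gene_id in sorted(hits_by_gene):
        call = classify_gene(gene_id, hits_by_gene[gene_id], e_value_cutoff)
        if call.family != "none":
            call = classify_subfamily(
                call, hits_by_gene[gene_id], e_value_cutoff, annotations
            )
        calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# chromosome distributions


def chromosome_count_matrix(
    records: Iterable[GeneRecord],
    family: str,
    chromosomes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Per-species x per-chromosome gene counts for one family.

    Returns ``(matrix, n_unanchored)``; unanchored genes are excluded
    from the matrix but tallied.  If ``chromosomes`` is given, any
    anchored record on a label outside it is an error.
    """
    recs = [r for r in records if r.family == family]
    unanchored = sum(1 for r in recs if not r.anchored or not r.chromosome)
    anchored = [r for r in recs if r.anchored and r.chromosome]
    if chromosomes is not None:
        bad = {r.chromosome for r in anchored} - set(chromosomes)
        if bad:
            raise ValueError(f"unknown chromosome labels: {sorted(bad)}")
    species = sorted({r.species for r in anchored})
    chroms = list(chromosomes) if chromosomes is not None else sorted(
        {r.chromosome for r in anchored}
    )
    mat = pd.DataFrame(0, index=species, columns=chroms, dtype=int)
    for r in anchored:
        mat.loc[r.species, r.chromosome] += 1
    return mat, unanchored


def chromosome_homogeneity_test(
    counts_a: Sequence[int], counts_b: Sequence[int]
) -> tuple[float, float, int]:
    """Chi-squared homogeneity test between two chromosome count vectors.

    Expected counts come from the pooled margins; no continuity
    correction; df = (#kept categories - 1).  Categories whose pooled
    count is zero are dropped (logged).

    Returns ``(chi2, p_value, df)``.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    pooled = a + b
    keep = pooled > 0
    if not keep.any() or a.sum() == 0 or b.sum() == 0:
        raise ValueError("all-zero margin: homogeneity test undefined")
    if not keep.all():
        logger.info("dropping %d zero-pooled categories", int((~keep).sum()))
        a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need >=2 non-empty categories")
    chi2, p, df, _ = stats.chi2_contingency(np.vstack([a, b]), correction=False)
    return float(chi2), float(p), int(df)


def correlation_distance_matrix(count_matrix: pd.DataFrame) -> np.ndarray:
    """Pairwise ``1 - Pearson r`` distances between rows.

    A constant row has no defined correlation; its distance to every
    other row is set to 1 (logged), and 0 to itself.
    """
    x = count_matrix.to_numpy(dtype=float)
    n = x.shape[0]
    sd = x.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning("%d constant rows: correlation distance set to 1",
                       int(const.sum()))
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    ok = ~const
    if ok.sum() >= 2:
        sub = np.corrcoef(x[ok])
        dist[np.ix_(ok, ok)] = 1.0 - sub
        np.fill_diagonal(dist, 0.0)
    return dist


def cluster_count_vectors(
    count_matrix: pd.DataFrame,
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of rows under 1 - Pearson distance.

    Returns the scipy linkage matrix and the leaf order as row labels.
    Rows are pre-sorted by label so equal-distance merges are stable.
    """
    if count_matrix.shape[0] < 2:
        raise ValueError("need >=2 rows to cluster")
    ordered = count_matrix.sort_index()
    dist = correlation_distance_matrix(ordered)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    leaves = hierarchy.leaves_list(link)
    return link, [str(ordered.index[i]) for i in leaves]
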