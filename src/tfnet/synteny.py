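"""Gene gain/loss categorization from homologous-set tables.

Each homologous set lists member genes per species.  Against a focal
species and its two direct ancestors, every focal gene is assigned
exactly one category:

* ``multi_copy`` — its set has >=2 members from some focal/ancestor
  species (takes precedence over the other categories);
* ``novel`` — its set has no ancestor member;
* ``conserved`` — single-copy in the focal species with ancestor
  support and no duplicated species.

Ancestor genes whose set has no focal member are ``lost`` (attributed
to the ancestor, i.e. to the focal sub-genome it contributed).

Outgroup species (e.g. *A. thaliana*) are carried for reporting but do
not affect category logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

CATEGORIES = ("novel", "conserved", "multi_copy", "lost")

DEFAULT_FOCAL = "B. napus"
DEFAULT_ANCESTORS = ("B. rapa", "B. oleracea")

#: ancestor species -> sub-genome it contributed to the focal genome
DEFAULT_ANCESTOR_SUBGENOME = {"B. rapa": "A", "B. oleracea": "C"}


@dataclass(frozen=True)
class HomologSet:
    set_id: str
    members: tuple[tuple[str, str], ...]  # (species, gene_id)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"set {self.set_id!r}: empty member list")

    def copies(self, species: str) -> list[str]:
        return [g for s, g in self.members if s == species]


@dataclass(frozen=True)
class CategoryCall:
    gene_id: str
    category: str
    species: str = ""
    sub_genome: str = "unplaced"
    family: str = ""
    subfamily: str = ""
    flagged: bool = False  # set when the call needed a precedence rule


def sub_genome_from_chromosome(chromosome: str) -> str:
    c = chromosome.lower()
    if c.startswith("chra"):
        return "A"
    if c.startswith("chrc"):
        return "C"
    return "unplaced"


def categorize(
    sets: Sequence[HomologSet],
    focal_species: str = DEFAULT_FOCAL,
    ancestor_species: Sequence[str] = DEFAULT_ANCESTORS,
    records: Mapping[str, object] | None = None,
    ancestor_subgenome: Mapping[str, str] | None = None,
) -> list[CategoryCall]:
    """Assign categories to focal genes and lost labels to ancestor genes.

    ``records`` optionally maps gene_id -> GeneRecord to fill in family,
    subfamily and sub-genome.  Raises if any gene occurs in two sets.
    """
    ancestors = list(ancestor_species)
    anc_sub = dict(ancestor_subgenome or DEFAULT_ANCESTOR_SUBGENOME)
    seen: dict[str, str] = {}
    calls: list[CategoryCall] = []

    def _meta(gene_id: str, species: str) -> dict:
        rec = (records or {}).get(gene_id)
        if rec is not None:
            sub = rec.sub_genome or sub_genome_from_chromosome(rec.chromosome)
            if sub in ("", "unplaced") and species in anc_sub:
                # ancestors map to the sub-genome they contributed
                sub = anc_sub[species]
            return {
                "species": species,
                "sub_genome": sub,
                "family": rec.family,
                "subfamily": rec.subfamily,
            }
        if species in anc_sub:
            return {"species": species, "sub_genome": anc_sub[species]}
        return {"species": species}

    for hset in sets:
        for _, gene_id in hset.members:
            if gene_id in seen and seen[gene_id] != hset.set_id:
                raise ValueError(
                    f"gene {gene_id!r} appears in sets "
                    f"{seen[gene_id]!r} and {hset.set_id!r}"
                )
            seen[gene_id] = hset.set_id

        focal = hset.copies(focal_species)
        anc_counts = {s: len(hset.copies(s)) for s in ancestors}
        n_ancestors = sum(anc_counts.values())
        duplicated = len(focal) >= 2 or any(c >= 2 for c in anc_counts.values())

        if not focal:
            # every ancestor member of a focal-free set is lost
            for s in ancestors:
                for g in hset.copies(s):
                    calls.append(CategoryCall(g, "lost", **_meta(g, s)))
            continue

        if duplicated:
            flag = n_ancestors == 0  # would also qualify as novel
            if flag:
                logger.info(
                    "set %s: no ancestor member but >=2 focal copies; "
                    "multi_copy takes precedence", hset.set_id,
                )
            for g in focal:
                calls.append(
                    CategoryCall(g, "multi_copy", flagged=flag,
                                 **_meta(g, focal_species))
                )
        elif n_ancestors == 0:
            calls.append(
                CategoryCall(focal[0], "novel", **_meta(focal[0], focal_species))
            )
        else:
            flag = any(c == 0 for c in anc_counts.values())
            if flag:
                logger.info(
                    "set %s: single-copy with only partial ancestor support; "
                    "called conserved", hset.set_id,
                )
            calls.append(
                CategoryCall(focal[0], "conserved", flagged=flag,
                             **_meta(focal[0], focal_species))
            )
    return calls


def category_summary(
    calls: Iterable[CategoryCall],
    family_sizes: Mapping[str, int] | None = None,
) -> dict:
    """Aggregate counts: per family x category, per sub-genome, and the
    unweighted mean per-family fraction of each category.

    ``family_sizes`` gives the focal-species family sizes used as
    fraction denominators; when omitted they default to the per-family
    totals of the three focal categories.  Mean fractions are reported
    as percentages rounded to one decimal; the pooled fraction (total
    count / total size) is reported alongside.
    """
    calls = list(calls)
    families = sorted({c.family for c in calls if c.family})
    by_fam_cat: dict[str, dict[str, int]] = {
        f: {c: 0 for c in CATEGORIES} for f in families
    }
    by_subgenome: dict[str, dict[str, int]] = {}
    for c in calls:
        if c.family:
            by_fam_cat[c.family][c.category] += 1
        sg = by_subgenome.setdefault(c.sub_genome, {k: 0 for k in CATEGORIES})
        sg[c.category] += 1

    focal_cats = ("novel", "conserved", "multi_copy")
    if family_sizes is None:
        family_sizes = {
            f: sum(by_fam_cat[f][c] for c in focal_cats) for f in families
        }

    mean_fraction_pct: dict[str, float] = {}
    pooled_fraction_pct: dict[str, float] = {}
    total_size = sum(family_sizes.get(f, 0) for f in families)
    for cat in focal_cats:
        fracs = [
            by_fam_cat[f][cat] / family_sizes[f]
            for f in families
            if family_sizes.get(f)
        ]
        mean_fraction_pct[cat] = (
            round(100.0 * sum(fracs) / len(fracs), 1) if fracs else 0.0
        )
        total = sum(by_fam_cat[f][cat] for f in families)
        pooled_fraction_pct[cat] = (
            round(100.0 * total / total_size, 1) if total_size else 0.0
        )

    totals = {
        cat: sum(1 for c in calls if c.category == cat) for cat in CATEGORIES
    }
    lost_by_subgenome = {
        sg: counts["lost"] for sg, counts in sorted(by_subgenome.items())
    }
    return {
        "per_family": by_fam_cat,
        "per_sub_genome": by_subgenome,
        "totals": totals,
        "lost_by_sub_genome": lost_by_subgenome,
        "mean_fraction_pct": mean_fraction_pct,
        "pooled_fraction_pct": pooled_fraction_pct,
        "family_sizes": dict(family_sizes),
    }
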