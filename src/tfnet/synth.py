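"""Synthetic-data generator: every input the pipeline consumes, with
machine-readable ground truth for parameter-recovery tests.

Everything is driven by one :class:`~tfnet.config.SynthConfig`; a fixed
seed fixes all outputs bit-for-bit.  The expression model is log-normal
FPKM around cluster-specific treatment means: each co-expression cluster
shares a baseline and a treatment-response archetype, so at zero
replicate noise the within-cluster expression rows are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cis import DEFAULT_MOTIFS, IUPAC, MotifDef
from .config import SynthConfig
from .deg import ExpressionMatrix
from .gonet import AnnotationTable
from .inventory import DomainHit, GeneRecord
from .synteny import HomologSet

FOCAL_SPECIES = "B. napus"
ANCESTOR_SPECIES = ("B. rapa", "B. oleracea")
_ANCESTOR_PREFIX = {"B. rapa": "Bra", "B. oleracea": "Bol"}

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticInventory:
    records: list[GeneRecord]
    ancestor_records: list[GeneRecord]
    domain_hits: dict[str, list[DomainHit]]
    promoters: dict[str, str]
    homolog_sets: list[HomologSet]
    ground_truth: dict


def _family_tag(family: str) -> str:
    return "".join(ch for ch in family if ch.isalnum())


def _make_domain_hits(
    gene_id: str, family: str, rng: np.random.Generator
) -> tuple[list[DomainHit], str]:
    """Rule-consistent domain hits plus the implied subfamily."""
    def ev() -> float:
        return float(10.0 ** rng.uniform(-30, -6))

    hits: list[DomainHit] = []
    if family == "AP2/EREBP":
        sub = rng.choice(["AP2", "RAV", "EREBP-unresolved"], p=[0.1, 0.1, 0.8])
        if sub == "AP2":
            hits += [
                DomainHit(gene_id, "AP2", 10, 70, ev()),
                DomainHit(gene_id, "AP2", 100, 160, ev()),
            ]
        elif sub == "RAV":
            hits += [
                DomainHit(gene_id, "AP2", 10, 70, ev()),
                DomainHit(gene_id, "B3", 120, 220, ev()),
            ]
        else:
            hits.append(DomainHit(gene_id, "AP2", 10, 70, ev()))
    elif family == "bZIP":
        sub = ""
        domain = "bZIP_1" if rng.random() < 0.8 else "bZIP_2"
        hits.append(DomainHit(gene_id, domain, 30, 90, ev()))
    elif family == "MYB":
        n_repeats = int(rng.choice([1, 2, 3, 4], p=[0.45, 0.45, 0.07, 0.03]))
        sub = {1: "1R", 2: "R2R3", 3: "3R", 4: "4R"}[n_repeats]
        for k in range(n_repeats):
            hits.append(
                DomainHit(gene_id, "MYB", 10 + 60 * k, 60 + 60 * k, ev())
            )
    elif family == "NAC":
        sub = ""
        hits.append(DomainHit(gene_id, "NAM", 5, 150, ev()))
    elif family == "WRKY":
        sub = str(rng.choice(["I", "II", "III"], p=[0.2, 0.6, 0.2]))
        core = "WRKYGQK"
        if rng.random() < 0.05:  # degenerate heptad variant
            core = str(rng.choice(["WKNY", "WKKY", "WRRY"])) + "GQK"
        if sub == "I":
            hits += [
                DomainHit(gene_id, "WRKY", 100, 160, ev(), "WRKYGQK"),
                DomainHit(gene_id, "WRKY", 220, 280, ev(), core),
                DomainHit(gene_id, "zinc_finger", 290, 320, ev(), "C2H2"),
            ]
        elif sub == "II":
            hits += [
                DomainHit(gene_id, "WRKY", 150, 210, ev(), core),
                DomainHit(gene_id, "zinc_finger", 220, 250, ev(), "C2H2"),
            ]
        else:
            hits += [
                DomainHit(gene_id, "WRKY", 150, 210, ev(), core),
                DomainHit(gene_id, "zinc_finger", 220, 250, ev(), "C2HC"),
            ]
    else:  # extra families get a generic single signature hit
        sub = ""
        hits.append(DomainHit(gene_id, "MYB", 10, 60, ev()))
    return hits, sub


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _plant_motifs(
    seq: str,
    motifs: Sequence[MotifDef],
    n_plant: int,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[str, int]]]:
    """Overwrite ``n_plant`` motif consensi at disjoint random positions.

    Returns the edited sequence and [(motif_name, 1-based position)].
    Degenerate consensus codes are concretized to a matching base.
    """
    occupied: list[tuple[int, int]] = []
    planted: list[tuple[str, int]] = []
    chars = list(seq)
    for _ in range(n_plant):
        motif = motifs[int(rng.integers(0, len(motifs)))]
        cons = motif.consensus
        for _attempt in range(50):
            pos = int(rng.integers(0, len(seq) - len(cons) + 1))
            span = (pos, pos + len(cons))
            if all(span[1] <= s or span[0] >= e for s, e in occupied):
                break
        else:
            continue
        occupied.append(span)
        for k, code in enumerate(cons):
            choices = sorted(IUPAC[code])
            chars[pos + k] = choices[int(rng.integers(0, len(choices)))]
        planted.append((motif.name, pos + 1))
    return "".join(chars), planted


def generate_inventory(config: SynthConfig) -> SyntheticInventory:
    """Gene records, domain hits, promoters and homologous sets."""
    rng = np.random.default_rng(config.seed)
    chroms = [f"chrA{i + 1:02d}" for i in range(config.n_chromosomes_A)] + [
        f"chrC{i + 1:02d}" for i in range(config.n_chromosomes_C)
    ]
    records: list[GeneRecord] = []
    ancestor_records: list[GeneRecord] = []
    domain_hits: dict[str, list[DomainHit]] = {}
    promoters: dict[str, str] = {}
    subfamilies: dict[str, str] = {}
    planted_motifs: dict[str, list[tuple[str, int]]] = {}

    for family in config.families:
        tag = _family_tag(family)
        for i in range(config.n_genes_per_family):
            gene_id = f"Bn{tag}g{i + 1:04d}"
            if rng.random() < config.unanchored_fraction:
                chrom, sub_genome, anchored = "", "unplaced", False
            else:
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                sub_genome = "A" if chrom.startswith("chrA") else "C"
                anchored = True
            hits, sub = _make_domain_hits(gene_id, family, rng)
            records.append(
                GeneRecord(
                    gene_id, FOCAL_SPECIES, family, sub, chrom, sub_genome,
                    anchored,
                )
            )
            domain_hits[gene_id] = hits
            subfamilies[gene_id] = sub
            seq, planted = _plant_motifs(
                _random_sequence(config.promoter_length, rng),
                DEFAULT_MOTIFS,
                config.n_motifs_per_promoter,
                rng,
            )
            promoters[gene_id] = seq
            planted_motifs[gene_id] = planted

    # homologous sets in planted category proportions
    sets: list[HomologSet] = []
    categories: dict[str, str] = {}
    set_counter = 0
    anc_counter = {s: 0 for s in ANCESTOR_SPECIES}

    def new_ancestor(species: str, family: str) -> str:
        anc_counter[species] += 1
        gid = f"{_ANCESTOR_PREFIX[species]}{_family_tag(family)}{anc_counter[species]:04d}"
        ancestor_records.append(GeneRecord(gid, species, family))
        return gid

    for family in config.families:
        fam_genes = [r.gene_id for r in records if r.family == family]
        n = len(fam_genes)
        n_novel = int(round(config.novel_fraction * n))
        n_conserved = int(round(config.conserved_fraction * n))
        order = list(rng.permutation(fam_genes))
        novel = order[:n_novel]
        conserved = order[n_novel:n_novel + n_conserved]
        multi = order[n_novel + n_conserved:]
        for g in novel:
            set_counter += 1
            sets.append(HomologSet(f"hs{set_counter:05d}", ((FOCAL_SPECIES, g),)))
            categories[g] = "novel"
        for g in conserved:
            set_counter += 1
            members = [(FOCAL_SPECIES, g)] + [
                (s, new_ancestor(s, family)) for s in ANCESTOR_SPECIES
            ]
            sets.append(HomologSet(f"hs{set_counter:05d}", tuple(members)))
            categories[g] = "conserved"
        # multi-copy genes are paired; an odd leftover gets a duplicated
        # ancestor instead so the >=2-copies rule still fires
        for k in range(0, len(multi) - 1, 2):
            set_counter += 1
            g1, g2 = multi[k], multi[k + 1]
            members = [(FOCAL_SPECIES, g1), (FOCAL_SPECIES, g2)]
            members.append((ANCESTOR_SPECIES[0], new_ancestor(ANCESTOR_SPECIES[0], family)))
            sets.append(HomologSet(f"hs{set_counter:05d}", tuple(members)))
            categories[g1] = categories[g2] = "multi_copy"
        if len(multi) % 2:
            g = multi[-1]
            set_counter += 1
            sp = ANCESTOR_SPECIES[0]
            members = (
                (FOCAL_SPECIES, g),
                (sp, new_ancestor(sp, family)),
                (sp, new_ancestor(sp, family)),
            )
            sets.append(HomologSet(f"hs{set_counter:05d}", members))
            categories[g] = "multi_copy"
        # lost: ancestor-only sets
        lost: list[str] = []
        for species in ANCESTOR_SPECIES:
            for _ in range(config.lost_per_ancestor):
                set_counter += 1
                gid = new_ancestor(species, family)
                sets.append(
                    HomologSet(f"hs{set_counter:05d}", ((species, gid),))
                )
                lost.append(gid)
        for gid in lost:
            categories[gid] = "lost"

    truth = {
        "subfamilies": subfamilies,
        "planted_motifs": planted_motifs,
        "categories": categories,
    }
    return SyntheticInventory(
        records, ancestor_records, domain_hits, promoters, sets, truth
    )


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    config: SynthConfig, inventory: SyntheticInventory
) -> tuple[ExpressionMatrix, dict]:
    """Control + treatments x replicates FPKM with planted clusters/DE.

    Cluster 0 is the null (non-responsive) cluster; clusters >= 1 carry a
    distinct response archetype whose non-zero entries are +-
    ``de_effect_log2fc``.  Ground truth: per-gene cluster labels and the
    planted DE table (gene x treatment signs).
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = [r.gene_id for r in inventory.records]
    treatments = list(config.treatments)
    n_t = len(treatments)

    # distinct archetypes for clusters 1..n_clusters (>=1 nonzero entry)
    archetypes: list[np.ndarray] = [np.zeros(n_t)]
    seen = {tuple(archetypes[0])}
    while len(archetypes) < config.n_clusters + 1:
        signs = rng.choice([-1.0, 0.0, 1.0], size=n_t, p=[0.3, 0.4, 0.3])
        if not signs.any():
            continue
        key = tuple(signs)
        if key in seen:
            continue
        seen.add(key)
        archetypes.append(signs * config.de_effect_log2fc)

    cluster_of: dict[str, int] = {}
    for g in genes:
        if rng.random() < config.de_fraction:
            cluster_of[g] = int(rng.integers(1, config.n_clusters + 1))
        else:
            cluster_of[g] = 0
    # baselines span a narrow log2 band: the noise statistic D is on the
    # raw FPKM scale, so wildly different baselines would let high-
    # expression replicate noise dominate low-expression signals
    baselines = {
        c: float(rng.uniform(6.5, 7.5)) for c in range(config.n_clusters + 1)
    }

    conditions = ["control"] + treatments
    samples = [
        f"{cond}_r{rep + 1}"
        for cond in conditions
        for rep in range(config.n_replicates)
    ]
    values = np.empty((len(genes), len(samples)))
    for gi, g in enumerate(genes):
        c = cluster_of[g]
        base = baselines[c]
        col = 0
        for ci, cond in enumerate(conditions):
            effect = 0.0 if cond == "control" else archetypes[c][ci - 1]
            for _rep in range(config.n_replicates):
                noise = rng.normal(0.0, config.noise_sd) if config.noise_sd else 0.0
                values[gi, col] = 2.0 ** (base + effect + noise)
                col += 1

    frame = pd.DataFrame(values, index=genes, columns=samples)
    meta = pd.DataFrame(
        {
            "condition": [s.rsplit("_r", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    matrix = ExpressionMatrix(frame, meta, control="control")

    de_signs = {
        g: {
            t: int(np.sign(archetypes[cluster_of[g]][ti]))
            for ti, t in enumerate(treatments)
            if archetypes[cluster_of[g]][ti] != 0
        }
        for g in genes
    }
    truth = {
        "clusters": cluster_of,
        "archetypes": [a.tolist() for a in archetypes],
        "de_signs": de_signs,
        "baselines": baselines,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# GO annotations, regulatory graph, homology map


def generate_go_and_regulatory(
    config: SynthConfig,
    inventory: SyntheticInventory,
    de_signs: Mapping[str, Mapping[str, int]] | None = None,
) -> tuple[AnnotationTable, nx.DiGraph, list[tuple[str, str]], dict]:
    """Family-biased GO annotations, a sparse regulatory graph with
    planted same-family triangles, and a cross-species homology map.

    When ``de_signs`` (from :func:`generate_expression`) is given, every
    planted DE gene additionally receives ``response to <treatment>``
    stimulus terms, so crucial-DEG selection is recoverable.
    """
    rng = np.random.default_rng(config.seed + 2)
    families = list(config.families)
    genes_by_family = {
        f: [r.gene_id for r in inventory.records if r.family == f]
        for f in families
    }

    # split the term universe into per-family pools
    pool_size = max(1, config.n_go_terms // len(families))
    pools = {
        f: [f"GO:BP:{fi * pool_size + k:04d}" for k in range(pool_size)]
        for fi, f in enumerate(families)
    }
    all_terms = [t for f in families for t in pools[f]]
    terms: dict[str, set[str]] = {}
    for f in families:
        for g in genes_by_family[f]:
            chosen: set[str] = set()
            for _ in range(config.go_terms_per_gene):
                if rng.random() < config.go_family_bias:
                    pool = pools[f]
                else:
                    pool = all_terms
                chosen.add(pool[int(rng.integers(0, len(pool)))])
            terms[g] = chosen
    if de_signs:
        for g, per_treatment in de_signs.items():
            for t in per_treatment:
                terms.setdefault(g, set()).add(f"response to {t}")
    annotations = AnnotationTable(
        terms, {r.gene_id for r in inventory.records}
    )

    # homology map: partner species gene per focal gene (subset)
    homology: list[tuple[str, str]] = []
    partner_of: dict[str, str] = {}
    for i, r in enumerate(inventory.records):
        if rng.random() < 0.5:
            partner = f"AT{i + 1:05d}"
            homology.append((partner, r.gene_id))
            partner_of[r.gene_id] = partner

    # regulatory graph: TF partners -> extra target genes (triangle-free
    # background), plus planted cyclic triangles among reserved
    # same-family TF nodes that carry no background edges
    graph = nx.DiGraph()
    partners_by_family = {
        f: sorted(
            partner_of[g] for g in genes_by_family[f] if g in partner_of
        )
        for f in families
    }
    reserved: set[str] = set()
    planted_triangles: list[tuple[str, str, str]] = []
    for f in families:
        avail = [p for p in partners_by_family[f] if p not in reserved]
        while len(planted_triangles) < config.n_planted_triangles and len(avail) >= 3:
            tri = tuple(sorted(avail[:3]))
            avail = avail[3:]
            reserved.update(tri)
            a, b, c = tri
            graph.add_edge(a, b)
            graph.add_edge(b, c)
            graph.add_edge(c, a)
            planted_triangles.append(tri)
        if len(planted_triangles) >= config.n_planted_triangles:
            break

    targets = [f"ATT{i:05d}" for i in range(1, 2 * len(partner_of) + 1)]
    for f in families:
        for p in partners_by_family[f]:
            if p in reserved:
                continue
            graph.add_node(p)
            n_out = int(rng.integers(1, 4))
            for _ in range(n_out):
                tgt = targets[int(rng.integers(0, len(targets)))]
                graph.add_edge(p, tgt)

    truth = {
        "pools": pools,
        "planted_triangles": planted_triangles,
        "partner_of": partner_of,
    }
    return annotations, graph, homology, truth


# ---------------------------------------------------------------------------
# fixture builder for printed-count summaries


def build_homolog_sets_from_counts(
    family_sizes: Mapping[str, int],
    focal_counts: Mapping[str, Mapping[str, int]],
    lost_counts: Mapping[str, Mapping[str, int]] | None = None,
) -> tuple[list[HomologSet], dict[str, GeneRecord]]:
    """Encode per-family category counts as concrete homologous sets.

    ``focal_counts[family]`` gives ``novel``/``conserved`` counts; the
    remainder up to ``family_sizes[family]`` becomes multi-copy.
    ``lost_counts[ancestor_species][family]`` plants ancestor-only sets.
    Returns the sets plus a gene -> GeneRecord map for attribution.
    """
    sets: list[HomologSet] = []
    records: dict[str, GeneRecord] = {}
    counter = {"set": 0, "anc": 0}

    def next_set() -> str:
        counter["set"] += 1
        return f"fx{counter['set']:05d}"

    def ancestor(species: str, family: str) -> str:
        counter["anc"] += 1
        gid = f"{_ANCESTOR_PREFIX[species]}x{counter['anc']:05d}"
        records[gid] = GeneRecord(gid, species, family)
        return gid

    for family, size in family_sizes.items():
        tag = _family_tag(family)
        fam_counts = focal_counts.get(family, {})
        n_novel = fam_counts.get("novel", 0)
        n_cons = fam_counts.get("conserved", 0)
        n_multi = size - n_novel - n_cons
        if n_multi < 0:
            raise ValueError(f"{family}: category counts exceed family size")
        gene_ids = [f"Bnfx{tag}{i:05d}" for i in range(1, size + 1)]
        for gid in gene_ids:
            records[gid] = GeneRecord(gid, FOCAL_SPECIES, family)
        idx = 0
        for _ in range(n_novel):
            sets.append(HomologSet(next_set(), ((FOCAL_SPECIES, gene_ids[idx]),)))
            idx += 1
        for _ in range(n_cons):
            members = [(FOCAL_SPECIES, gene_ids[idx])] + [
                (s, ancestor(s, family)) for s in ANCESTOR_SPECIES
            ]
            sets.append(HomologSet(next_set(), tuple(members)))
            idx += 1
        multi = gene_ids[idx:]
        for k in range(0, len(multi) - 1, 2):
            sets.append(
                HomologSet(
                    next_set(),
                    ((FOCAL_SPECIES, multi[k]), (FOCAL_SPECIES, multi[k + 1])),
                )
            )
        if len(multi) % 2:
            sp = ANCESTOR_SPECIES[0]
            sets.append(
                HomologSet(
                    next_set(),
                    (
                        (FOCAL_SPECIES, multi[-1]),
                        (sp, ancestor(sp, family)),
                        (sp, ancestor(sp, family)),
                    ),
                )
            )
    for species, per_family in (lost_counts or {}).items():
        for family, n_lost in per_family.items():
            for _ in range(n_lost):
                gid = ancestor(species, family)
                sets.append(HomologSet(next_set(), ((species, gid),)))
    return sets, records
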