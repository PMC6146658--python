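"""Promoter scanning for cis-element consensus motifs.

Motifs are exact IUPAC-degenerate consensi (no PWM scoring).  Promoters
are fixed-length upstream windows; hits on the reverse strand are
reported in forward coordinates.

The shipped default motif table is *configuration*, not ground truth:
consensus strings follow common PlantCARE-style definitions and are
meant to be edited per study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

SEQUENCE_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class MotifDef:
    """A named consensus motif."""

    name: str
    consensus: str
    associated_response: str = ""

    def __post_init__(self) -> None:
        cons = self.consensus.upper()
        if not cons:
            raise ValueError(f"motif {self.name!r}: empty consensus")
        bad = set(cons) - set(IUPAC)
        if bad:
            raise ValueError(
                f"motif {self.name!r}: non-IUPAC characters {sorted(bad)}"
            )
        object.__setattr__(self, "consensus", cons)


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    position: int  # 1-based offset of the match window in the promoter
    strand: str  # '+' or '-'


#: editable defaults (PlantCARE-style consensi) — configuration, not data
DEFAULT_MOTIFS: tuple[MotifDef, ...] = (
    MotifDef("ABRE", "ACGTG", "ABA responsiveness"),
    MotifDef("HSE", "AAAAAATTTC", "heat responsiveness"),
    MotifDef("LTR", "CCGAAA", "low-temperature responsiveness"),
    MotifDef("MBS", "CAACTG", "drought inducibility (MYB binding)"),
    MotifDef("TCA-element", "CCATCTTTTT", "salicylic acid responsiveness"),
    MotifDef("TGACG-motif", "TGACG", "MeJA responsiveness"),
    MotifDef("TC-rich repeats", "ATTTTCTTCA", "defense and stress"),
    MotifDef("P-box", "CCTTTTG", "gibberellin responsiveness"),
    MotifDef("GARE-motif", "TCTGTTG", "gibberellin responsiveness"),
    MotifDef("TGA-element", "AACGAC", "auxin responsiveness"),
)


def reverse_complement(consensus: str) -> str:
    """IUPAC-aware reverse complement."""
    return consensus.upper().translate(_COMPLEMENT)[::-1]


def _matches(seq: str, pos: int, consensus: str) -> bool:
    for offset, code in enumerate(consensus):
        base = seq[pos + offset]
        if base == "N":
            if code != "N":
                return False
        elif base not in IUPAC[code]:
            return False
    return True


def _validate_sequence(seq: str) -> str:
    up = seq.upper()
    for i, base in enumerate(up):
        if base not in SEQUENCE_ALPHABET:
            raise ValueError(f"invalid sequence character {base!r} at offset {i}")
    return up


def scan_sequence(
    seq: str,
    motifs: Sequence[MotifDef],
    gene_id: str = "",
    both_strands: bool = True,
) -> list[MotifHit]:
    """All exact consensus occurrences in ``seq`` (overlaps allowed).

    Reverse-strand hits are found by scanning the reverse complement of
    the consensus on the forward sequence; ``position`` is always the
    1-based forward coordinate of the match window start.
    """
    up = _validate_sequence(seq)
    hits: list[MotifHit] = []
    for motif in motifs:
        patterns = [(motif.consensus, "+")]
        if both_strands:
            patterns.append((reverse_complement(motif.consensus), "-"))
        for pattern, strand in patterns:
            m = len(pattern)
            for pos in range(len(up) - m + 1):
                if _matches(up, pos, pattern):
                    hits.append(MotifHit(gene_id, motif.name, pos + 1, strand))
    hits.sort(key=lambda h: (h.motif, h.position, h.strand))
    return hits


def scan_promoters(
    promoters: Mapping[str, str],
    motifs: Sequence[MotifDef],
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan every promoter in a gene -> sequence mapping."""
    out: list[MotifHit] = []
    for gene_id in sorted(promoters):
        out.extend(
            scan_sequence(promoters[gene_id], motifs, gene_id, both_strands)
        )
    return out


def element_distribution(
    hits: Iterable[MotifHit],
    records: Iterable,
) -> dict[str, pd.DataFrame]:
    """Per-family motif-presence proportions plus chromosome/subfamily counts.

    A gene counts once per motif regardless of hit multiplicity.
    ``records`` are GeneRecords carrying family/subfamily/chromosome.

    Returns a dict with keys ``family_proportions`` (family x motif,
    values in [0,1]), ``chromosome_counts`` and ``subfamily_counts``
    (gene-presence counts).
    """
    recs = {r.gene_id: r for r in records}
    present: set[tuple[str, str]] = set()
    for h in hits:
        if h.gene_id not in recs:
            raise KeyError(f"hit references unknown gene {h.gene_id!r}")
        present.add((h.gene_id, h.motif))

    motifs = sorted({m for _, m in present})
    families = sorted({r.family for r in recs.values() if r.family})
    fam_sizes = {f: sum(1 for r in recs.values() if r.family == f) for f in families}

    prop = pd.DataFrame(0.0, index=families, columns=motifs)
    chroms = sorted({r.chromosome for r in recs.values() if r.chromosome})
    chrom_counts = pd.DataFrame(0, index=chroms, columns=motifs, dtype=int)
    subfams = sorted(
        {(r.family, r.subfamily) for r in recs.values() if r.subfamily}
    )
    sub_index = [f"{f}/{s}" for f, s in subfams]
    sub_counts = pd.DataFrame(0, index=sub_index, columns=motifs, dtype=int)

    for gene_id, motif in sorted(present):
        r = recs[gene_id]
        if r.family:
            prop.loc[r.family, motif] += 1
        if r.chromosome:
            chrom_counts.loc[r.chromosome, motif] += 1
        if r.subfamily:
            sub_counts.loc[f"{r.family}/{r.subfamily}", motif] += 1

    for f in families:
        if fam_sizes[f]:
            prop.loc[f] /= fam_sizes[f]
    return {
        "family_proportions": prop,
        "chromosome_counts": chrom_counts,
        "subfamily_counts": sub_counts,
    }
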