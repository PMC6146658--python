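"""Pipeline and synthetic-data configuration objects.

Both configs are plain dataclasses validated on construction; every
invalid field is reported by name.  YAML/JSON loading lives in
:mod:`tfnet.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

DEFAULT_FAMILIES = ("AP2/EREBP", "bZIP", "MYB", "NAC", "WRKY")
DEFAULT_TREATMENTS = ("cold", "heat", "drought", "salt", "ABA")

#: default reconstruction of the stimulus-response BP keyword list used
#: for crucial-DEG selection (a configured approximation, not a
#: published list)
DEFAULT_CRUCIAL_TERMS = (
    "response to cold",
    "response to heat",
    "response to water deprivation",
    "response to salt stress",
    "response to abscisic acid",
    "response to stress",
    "response to abiotic stimulus",
)


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass
class PipelineConfig:
    gcc_rho: float = 0.5
    gcc_threshold: float = 0.94
    deg_prob_threshold: float = 0.6
    deg_log2fc_threshold: float = 1.0
    deg_fc_inclusive: bool = True
    fdr_alpha: float = 0.05
    promoter_length: int = 1500
    pseudocount: float = 1.0
    crucial_go_terms: tuple[str, ...] = DEFAULT_CRUCIAL_TERMS
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    control: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.gcc_rho >= 0, "gcc_rho", "must be >= 0")
        _require(0 < self.gcc_threshold <= 1, "gcc_threshold", "must be in (0, 1]")
        _require(
            0 < self.deg_prob_threshold <= 1,
            "deg_prob_threshold", "must be in (0, 1]",
        )
        _require(
            self.deg_log2fc_threshold >= 0,
            "deg_log2fc_threshold", "must be >= 0",
        )
        _require(0 < self.fdr_alpha <= 1, "fdr_alpha", "must be in (0, 1]")
        _require(self.promoter_length > 0, "promoter_length", "must be > 0")
        _require(self.pseudocount > 0, "pseudocount", "must be > 0")


@dataclass
class SynthConfig:
    """Knobs for the synthetic-data generator."""

    n_genes_per_family: int = 20
    families: tuple[str, ...] = DEFAULT_FAMILIES
    n_chromosomes_A: int = 10
    n_chromosomes_C: int = 9
    unanchored_fraction: float = 0.1
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    n_replicates: int = 3
    n_clusters: int = 4
    de_fraction: float = 0.3
    de_effect_log2fc: float = 2.0
    noise_sd: float = 0.25
    n_go_terms: int = 40
    go_family_bias: float = 0.8
    go_terms_per_gene: int = 3
    novel_fraction: float = 0.08
    conserved_fraction: float = 0.09
    lost_per_ancestor: int = 5
    n_planted_triangles: int = 6
    n_motifs_per_promoter: int = 2
    promoter_length: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes_per_family", "n_chromosomes_A", "n_chromosomes_C",
            "n_replicates", "n_clusters",
        ):
            _require(getattr(self, name) >= 1, name, "must be >= 1")
        for name in (
            "unanchored_fraction", "go_family_bias", "de_fraction",
            "novel_fraction", "conserved_fraction",
        ):
            v = getattr(self, name)
            _require(0 <= v <= 1, name, "must be in [0, 1]")
        _require(
            self.novel_fraction + self.conserved_fraction <= 1,
            "novel_fraction", "novel + conserved fractions exceed 1",
        )
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.de_effect_log2fc >= 0, "de_effect_log2fc", "must be >= 0")
        _require(self.n_go_terms >= 1, "n_go_terms", "must be >= 1")
        _require(self.promoter_length > 0, "promoter_length", "must be > 0")
        _require(len(self.families) >= 1, "families", "must be non-empty")
        _require(len(self.treatments) >= 1, "treatments", "must be non-empty")
        _require(
            self.lost_per_ancestor >= 0, "lost_per_ancestor", "must be >= 0"
        )
        _require(
            self.n_planted_triangles >= 0,
            "n_planted_triangles", "must be >= 0",
        )


def config_from_mapping(cls, data: dict):
    """Build a config dataclass from a dict, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)
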