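"""End-to-end analysis orchestration.

``run_analysis`` executes the full study workflow on a configured matrix:
heuristic search, homoplasy statistics on a best tree, strict consensus,
decay indices, optional synapomorphy mapping under an outgroup rooting,
an optional reduced rerun with taxa deleted, and the optional tail
scenario.  Identical config + seed reproduces the report exactly; every
number in it is recomputable from the logged seeds and inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

from .matrix import NEXUS, TSV, CharacterMatrix, parse_matrix, prune_taxa
from .mapping import synapomorphy_list
from .parsimony import homoplasy_stats
from .search import SearchConfig, SearchResult, heuristic_search, strict_consensus
from .support import decay_table
from .tail import (
    encode_tail_characters,
    load_hemicaudotheca_taxa,
    load_reference_tree,
    load_tail_table,
    map_tail_changes,
    parse_tail_table,
)
from .trees import Tree

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "run_analysis",
    "run_tail_scenario",
    "load_study_matrix",
    "StudyMatrixUnavailable",
]


class StudyMatrixUnavailable(FileNotFoundError):
    pass


def load_study_matrix(path: str | Path | None = None) -> CharacterMatrix:
    """Load the transcribed coelurosaurian study matrix.

    The published matrix ships only as supplementary material to the
    source study and must be transcribed by the user (see
    ``data/coelurosaur_matrix_template.nex`` for the dialect).  Looks at
    ``path`` if given, else ``data/coelurosaur_matrix.nex`` inside the
    installed package.
    """
    from importlib import resources

    if path is not None:
        p = Path(path)
        if not p.exists():
            raise StudyMatrixUnavailable(f"no matrix file at {p}")
        return parse_matrix(p.read_text(), NEXUS)
    res = resources.files("morphpars.data").joinpath("coelurosaur_matrix.nex")
    if not res.is_file():
        raise StudyMatrixUnavailable(
            "the study matrix transcription (data/coelurosaur_matrix.nex) is "
            "not installed; transcribe the supplementary data matrix using "
            "data/coelurosaur_matrix_template.nex as the dialect reference"
        )
    return parse_matrix(res.read_text(), NEXUS)


@dataclass
class AnalysisConfig:
    matrix_file: str | None = None
    matrix_format: str = "nexus"  # nexus | tsv
    drop_taxa: list[str] = field(default_factory=list)
    outgroup: str | None = None  # default: first matrix taxon
    replicates: int = 50
    seed: int = 0
    swap: str = "tbr"
    maxtrees: int | None = None
    collapse: str = "min"
    compute_decay: bool = True
    tail_table_file: str | None = None  # None -> packaged study table

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Flat key=value config file; '#' comments; drop_taxa comma-split."""
        cfg = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "drop_taxa":
                cfg.drop_taxa = [t.strip() for t in value.split(",") if t.strip()]
            elif key in ("replicates", "seed"):
                setattr(cfg, key, int(value))
            elif key == "maxtrees":
                cfg.maxtrees = None if value.lower() in ("none", "0") else int(value)
            elif key == "compute_decay":
                cfg.compute_decay = value.lower() in ("1", "true", "yes")
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        return cfg


def _run_stats(matrix: CharacterMatrix, config: AnalysisConfig, label: str) -> dict:
    sconf = SearchConfig(
        replicates=config.replicates,
        seed=config.seed,
        swap=config.swap,
        maxtrees=config.maxtrees,
        collapse=config.collapse,
    )
    result = heuristic_search(matrix, sconf)
    best_tree = result.mpt_set[0]
    stats = homoplasy_stats(matrix, best_tree)
    consensus = strict_consensus(result.mpt_set)
    block: dict[str, Any] = {
        "label": label,
        "n_taxa": matrix.n_taxa,
        "n_char": matrix.n_char,
        "best_length": result.best_length,
        "mpt_count": result.mpt_count,
        "collapse_rule": config.collapse,
        "CI": stats.CI,
        "HI": stats.HI,
        "RI": stats.RI,
        "RC": stats.RC,
        "consensus_newick": consensus.newick(),
        "replicate_log": result.replicate_log,
        "island_count": result.island_count,
        "truncated": result.truncated,
    }
    if config.compute_decay:
        sup = decay_table(matrix, result, sconf)
        block["decay_table"] = [
            {"clade": sorted(r.bipartition), "decay": r.decay} for r in sup
        ]
    block["_result"] = result
    return block


def run_tail_scenario(tail_table_file: str | None = None) -> dict:
    """Tail-character mapping on the packaged reference phylogeny."""
    if tail_table_file is None:
        records = load_tail_table()
    else:
        records = parse_tail_table(Path(tail_table_file).read_text())
    tree = load_reference_tree()
    tail_matrix = encode_tail_characters(
        records,
        extra_states=load_hemicaudotheca_taxa(),
        keep_taxa=set(tree.labels.values()),
    )
    changes = map_tail_changes(tree, tail_matrix)
    return {
        "n_records": len(records),
        "dropped_taxa": tail_matrix.meta["dropped_taxa"],
        "changes": [
            {
                "character": c.character,
                "clade": sorted(c.clade),
                "from": c.from_state,
                "to": c.to_state,
            }
            for c in changes
        ],
    }


@dataclass
class AnalysisReport:
    full: dict
    reduced: dict | None
    synapomorphies: list[dict] | None
    tail: dict | None
    provenance: dict

    def to_json(self, **kw) -> str:
        def strip(block):
            if isinstance(block, dict):
                return {k: strip(v) for k, v in block.items() if not k.startswith("_")}
            if isinstance(block, list):
                return [strip(x) for x in block]
            return block

        return json.dumps(strip(asdict(self)), indent=2, **kw)


def run_analysis(
    config: AnalysisConfig | str | Path,
    matrix: CharacterMatrix | None = None,
    with_tail: bool = False,
) -> AnalysisReport:
    """Run the full (and optionally reduced) analysis per ``config``.

    ``matrix`` may be passed directly (e.g. a simulated one); otherwise it
    is read from ``config.matrix_file``.
    """
    if not isinstance(config, AnalysisConfig):
        config = AnalysisConfig.from_file(config)
    checksum = None
    if matrix is None:
        if config.matrix_file is None:
            raise ValueError("config names no matrix file and none was supplied")
        text = Path(config.matrix_file).read_text()
        checksum = hashlib.sha256(text.encode()).hexdigest()
        matrix = parse_matrix(text, NEXUS if config.matrix_format == "nexus" else TSV)

    full = _run_stats(matrix, config, "full")

    reduced = None
    if config.drop_taxa:
        reduced = _run_stats(prune_taxa(matrix, config.drop_taxa), config, "reduced")

    synapo = None
    outgroup = config.outgroup or matrix.taxa[0]
    result: SearchResult = full["_result"]
    consensus = strict_consensus(result.mpt_set)
    if outgroup in matrix.taxa:
        rooted = consensus.root_with_outgroup(outgroup)
        synapo = []
        for node, leafset in rooted.clades().items():
            if rooted.is_leaf(node) or node == rooted.root:
                continue
            for rec in synapomorphy_list(rooted, matrix, node):
                synapo.append(
                    {
                        "clade": sorted(rec.clade),
                        "character": rec.character,
                        "state": rec.state,
                        "support_mode": rec.support_mode,
                    }
                )

    tail = run_tail_scenario(config.tail_table_file) if with_tail else None

    report = AnalysisReport(
        full=full,
        reduced=reduced,
        synapomorphies=synapo,
        tail=tail,
        provenance={
            "seed": config.seed,
            "replicates": config.replicates,
            "swap": config.swap,
            "collapse": config.collapse,
            "outgroup": outgroup,
            "drop_taxa": config.drop_taxa,
            "matrix_sha256": checksum,
        },
    )
    return report
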