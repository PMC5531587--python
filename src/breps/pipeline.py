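"""End-to-end pattern generation: flatfile in, pattern database out.

Chains the six pipeline steps: data selection, all-vs-all distances,
complete-linkage clustering, per-node MSA + pattern construction (standard
and PAM250-extended), consensus-EC annotation, verification with PPV-based
exclusion, and final database build.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from . import data_selection as ds
from .clustering import ClusterTree, complete_linkage, select_pattern_nodes
from .db import build_database
from .distances import AlignerAdapter, IdentityStubAligner, all_vs_all
from .ec import ProposedEC, consensus_annotation
from .msa import MsaAdapter, StubMsaAligner, run_msa
from .patterns import (
    Pattern,
    PatternConfig,
    build_pattern,
    derive_similarity_sets,
    extend_pattern,
)
from .records import SequenceRecord, WorkingSet
from .verification import VerificationReport, filter_patterns, verify_all

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline parameters in one place."""

    filters: ds.FilterConfig = field(default_factory=ds.FilterConfig)
    pattern: PatternConfig = field(default_factory=PatternConfig)
    max_length_deviation: float = 0.25
    evalue_ceiling: float = 1e-3
    min_leaves: int = 3
    max_height: float | None = None
    similarity_threshold: float = 0.5
    ppv_cutoff: float = 1.0
    ec_match_mode: str = "fuzzy"
    release_tag: str = "synthetic"


@dataclass
class PipelineResult:
    working_set: WorkingSet
    tree: ClusterTree | None
    patterns: list[tuple[Pattern, ProposedEC]]
    report: VerificationReport | None
    kept: list[tuple[str, str]]
    db_path: Path | None


def generate_patterns(
    working_set: WorkingSet,
    config: PipelineConfig,
    aligner: AlignerAdapter | None = None,
    msa: MsaAdapter | None = None,
) -> tuple[ClusterTree | None, list[tuple[Pattern, ProposedEC]]]:
    """Steps B-D: distances, clustering, per-node patterns + annotation."""
    records = working_set.pattern_records
    if len(records) < 2:
        return None, []
    aligner = aligner or IdentityStubAligner()
    msa = msa or StubMsaAligner()
    matrix = all_vs_all(records, aligner, evalue_ceiling=config.evalue_ceiling)
    tree = complete_linkage(matrix)
    nodes = select_pattern_nodes(
        tree, min_leaves=config.min_leaves, max_height=config.max_height
    )
    by_acc = {r.accession: r for r in records}
    sim_sets = derive_similarity_sets(threshold=config.similarity_threshold)
    out: list[tuple[Pattern, ProposedEC]] = []
    for i, node in enumerate(nodes):
        members = [by_acc[a] for a in node.accessions]
        alignment = run_msa(members, msa)
        pattern = build_pattern(
            alignment.columns(),
            config.pattern,
            pattern_id=f"BP{i:05d}",
            origin_node=",".join(node.accessions[:1]) + f"+{node.n_leaves - 1}",
        )
        if pattern is None:
            logger.info("node %d below informative-position gate, skipped", i)
            continue
        proposed = consensus_annotation(
            [m.ec_sets[0] for m in members],
            accessions=[m.accession for m in members],
        )
        out.append((pattern, proposed))
        out.append((extend_pattern(pattern, sim_sets), proposed))
    return tree, out


def run_pipeline(
    flatfile: str | Path,
    uniref: str | Path | None,
    out_db: str | Path | None,
    config: PipelineConfig | None = None,
    aligner: AlignerAdapter | None = None,
    msa: MsaAdapter | None = None,
) -> PipelineResult:
    """Run the full protocol from a flatfile (+ optional cluster table)."""
    config = config or PipelineConfig()
    with open(flatfile) as fh:
        all_records = ds.parse_flatfile(fh)
    seeds = ds.apply_seed_filters(all_records, config.filters)
    if uniref is not None:
        with open(uniref) as fh:
            clusters = ds.read_uniref_table(fh)
        enriched = ds.enrich_seeds(
            seeds, all_records, clusters, config.max_length_deviation
        )
    else:
        enriched = []
    working_set = ds.build_working_set(seeds, enriched, all_records)
    logger.info(
        "working set: %d seeds, %d enriched, %d non-enzymes",
        len(working_set.seeds), len(working_set.enriched),
        len(working_set.non_enzymes),
    )
    tree, patterns = generate_patterns(working_set, config, aligner, msa)
    report = None
    kept: list[tuple[str, str]] = []
    if patterns:
        report = verify_all(patterns, working_set, mode=config.ec_match_mode)
        kept = filter_patterns(report.per_pattern, cutoff=config.ppv_cutoff)
    db_path = None
    if out_db is not None:
        kept_set = set(kept)
        entries = [
            (p, proposed, report.per_pattern[(p.id, p.flavor)])
            for p, proposed in patterns
            if (p.id, p.flavor) in kept_set
        ]
        db_path = build_database(
            entries,
            out_db,
            metadata={
                "release_tag": config.release_tag,
                "build_parameters": {
                    "filters": asdict(config.filters),
                    "pattern": asdict(config.pattern),
                    "max_length_deviation": config.max_length_deviation,
                    "evalue_ceiling": config.evalue_ceiling,
                    "min_leaves": config.min_leaves,
                    "max_height": config.max_height,
                    "similarity_threshold": config.similarity_threshold,
                    "ppv_cutoff": config.ppv_cutoff,
                    "ec_match_mode": config.ec_match_mode,
                },
                "n_seeds": len(working_set.seeds),
                "n_enriched": len(working_set.enriched),
                "n_non_enzymes": len(working_set.non_enzymes),
            },
        )
    return PipelineResult(
        working_set=working_set,
        tree=tree,
        patterns=patterns,
        report=report,
        kept=kept,
        db_path=db_path,
    )
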