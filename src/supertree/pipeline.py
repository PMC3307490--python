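"""End-to-end orchestration: standardize -> encode -> weight -> search ->
support -> date -> macroevolution/conservation, from a single declarative
configuration with reproducible seeds.

The paper-style analysis variants select which evidence enters the matrix:
``full`` (literature + gene trees + taxonomy seed), ``literature-only``,
``genes-only`` (each still seeded), and ``no-seed`` (all evidence, no
taxonomy tree).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import conservation as conservation_mod
from . import macro as macro_mod
from ._tree_utils import leaf_labels
from .datedtree import DatedTree
from .dating import date_tree
from .mrp import MRPMatrix, assign_weights, matrix_from_records, write_nexus
from .search import SearchConfig, SearchResult, ratchet_search
from .simulate import Scenario, ScenarioConfig, generate_scenario
from .sources import MOLECULAR_GENE_CATEGORY, SourceTreeRecord, write_records_nexus
from .support import mean_rqs, partition_metric, resolution, rqs_per_node

VARIANTS = ("full", "literature-only", "genes-only", "no-seed")
SEED_SOURCE_ID = "TAXONOMY"


@dataclass
class RunConfig:
    """A complete, declarative run description."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    variant: str = "full"
    search: SearchConfig = field(default_factory=SearchConfig)
    dating_mode: str = "weighted-mean"
    bin_width: float = 0.25
    include_root_stem: bool = False
    out_dir: Optional[str] = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


def gene_records(scenario: Scenario) -> list[SourceTreeRecord]:
    """Wrap the scenario's gene trees as rooted molecular source records."""
    return [
        SourceTreeRecord(
            tree=tree, rooted=True, publication_id=name,
            data_category=MOLECULAR_GENE_CATEGORY, gene_name=name,
        )
        for name, tree in scenario.gene_trees
    ]


def select_sources(scenario: Scenario, variant: str) -> tuple:
    """(records entering the matrix, records scored by rQS, seed id or None)."""
    lit = list(scenario.literature)
    genes = gene_records(scenario)
    if variant == "full":
        evidence = lit + genes
        seed = scenario.seed_tree
    elif variant == "literature-only":
        evidence, seed = lit, scenario.seed_tree
    elif variant == "genes-only":
        evidence, seed = genes, scenario.seed_tree
    else:  # no-seed
        evidence, seed = lit + genes, None
    matrix_records = evidence + ([seed] if seed is not None else [])
    return matrix_records, evidence, (SEED_SOURCE_ID if seed is not None else None)


def category_counts(records: Sequence[SourceTreeRecord]) -> dict:
    """Distinct source trees (publications) per literature data category."""
    pubs: dict = {}
    for rec in records:
        if rec.data_category == MOLECULAR_GENE_CATEGORY:
            continue
        pubs.setdefault(rec.data_category, set()).add(rec.publication_id)
    return {cat: len(ids) for cat, ids in pubs.items()}


def build_matrix(records: Sequence[SourceTreeRecord], seed_id: Optional[str]) -> MRPMatrix:
    matrix = matrix_from_records(records)
    counts = category_counts(
        [r for r in records if r.publication_id != seed_id]
    )
    assign_weights(matrix, counts, seed_source_id=seed_id)
    return matrix


def run_pipeline(config: RunConfig) -> dict:
    """Execute one full analysis; returns (and optionally writes) the manifest."""
    scenario = generate_scenario(config.scenario)
    matrix_records, evidence, seed_id = select_sources(scenario, config.variant)
    matrix = build_matrix(matrix_records, seed_id)

    start = scenario.seed_tree.tree if seed_id is not None else None
    result: SearchResult = ratchet_search(matrix, config.search, start_tree=start)
    consensus = result.consensus

    supports = rqs_per_node(consensus, evidence)
    rqs_mean, rqs_se = mean_rqs(supports)

    dated = date_tree(
        consensus, scenario.gene_trees, scenario.calibrations, mode=config.dating_mode
    )
    binary = macro_mod.resolve_polytomies_erm(dated, rng_seed=config.scenario.rng_seed)

    curve = macro_mod.ltt(binary)
    gamma = macro_mod.gamma_stat(binary)
    rates = macro_mod.binned_rates(binary, width=config.bin_width)
    segmented = (
        macro_mod.segmented_fit(curve) if len(curve.event_times) >= 6 else None
    )

    scores = conservation_mod.conservation_scores(
        binary, scenario.threat_categories,
        include_root_stem=config.include_root_stem,
        root_stem_age=None if not config.include_root_stem else binary.root_age,
    )
    ranking = conservation_mod.rank_table(scores)

    truth_distance = partition_metric(consensus, scenario.true_tree.tree)
    age_correlation = _age_correlation(dated, scenario.true_tree)

    manifest = {
        "variant": config.variant,
        "rng_seed": config.scenario.rng_seed,
        "n_taxa": matrix.n_taxa,
        "n_characters": matrix.n_characters,
        "mp_score": result.score,
        "n_mp_trees": len(result.mp_trees),
        "trace": result.trace,
        "resolution": resolution(consensus),
        "mean_rqs": rqs_mean,
        "se_rqs": rqs_se,
        "partition_metric_to_truth": truth_distance,
        "age_correlation_to_truth": age_correlation,
        "gamma": gamma.gamma,
        "gamma_p": gamma.p_two_tailed,
        "segmented_breakpoints": segmented.breakpoints if segmented else None,
        "config": _config_dict(config),
    }

    if config.out_dir:
        _write_outputs(
            config.out_dir, scenario, matrix, result, supports, dated,
            binary, curve, rates, ranking, manifest,
        )
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def _age_correlation(dated: DatedTree, truth: DatedTree) -> Optional[float]:
    """Pearson r between estimated and true ages over matching clades."""
    true_ages = {
        clade: node.age for node, clade in truth.clades().items() if not node.is_leaf()
    }
    xs, ys = [], []
    for node, clade in dated.clades().items():
        if node.is_leaf():
            continue
        if clade in true_ages:
            xs.append(node.age)
            ys.append(true_ages[clade])
    if len(xs) < 3 or np.std(xs) == 0 or np.std(ys) == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_outputs(out_dir, scenario, matrix, result, supports, dated,
                   binary, curve, rates, ranking, manifest) -> None:
    os.makedirs(out_dir, exist_ok=True)

    write_nexus(matrix, os.path.join(out_dir, "matrix.nex"))
    write_records_nexus(
        scenario.literature + [scenario.seed_tree],
        os.path.join(out_dir, "sources.nex"),
    )
    tl = dendropy.TreeList(result.mp_trees, taxon_namespace=result.mp_trees[0].taxon_namespace)
    tl.write(path=os.path.join(out_dir, "mp_trees.nex"), schema="nexus")
    result.consensus.write(path=os.path.join(out_dir, "consensus.nex"), schema="nexus")

    pd.DataFrame(
        [
            {
                "node_id": s.node_id, "n_support": s.n_support,
                "n_conflict": s.n_conflict, "n_equivocal": s.n_equivocal,
                "rqs": s.rqs,
            }
            for s in supports
        ]
    ).to_csv(os.path.join(out_dir, "rqs.csv"), index=False)

    dated.write_nexus(os.path.join(out_dir, "dated.nex"))
    dated.ages_frame().to_csv(os.path.join(out_dir, "node_ages.csv"), index=False)
    pd.DataFrame(
        {"time_ma": curve.event_times, "lineages": curve.lineage_counts}
    ).to_csv(os.path.join(out_dir, "ltt.csv"), index=False)
    pd.DataFrame(
        {
            "bin_start_ma": rates.bin_edges[:-1],
            "bin_end_ma": rates.bin_edges[1:],
            "events": rates.events,
            "exposure": rates.exposure,
            "rate": rates.rates,
        }
    ).to_csv(os.path.join(out_dir, "rates.csv"), index=False)
    ranking.to_csv(os.path.join(out_dir, "conservation.csv"), index=False)

    files = sorted(
        f for f in os.listdir(out_dir)
        if f != "manifest.json" and os.path.isfile(os.path.join(out_dir, f))
    )
    manifest = dict(manifest)
    manifest["files"] = {f: _sha256(os.path.join(out_dir, f)) for f in files}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def compare_variants(trees: Sequence[dendropy.Tree], labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Pairwise comparison matrix: shared-taxon counts above the diagonal,
    normalized partition distances below it (NA where < 4 taxa are shared)."""
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    labels = list(labels) if labels else [f"tree{i + 1}" for i in range(len(trees))]
    n = len(trees)
    cells = [[None] * n for _ in range(n)]
    leafsets = [frozenset(leaf_labels(t)) for t in trees]
    for i in range(n):
        for j in range(i + 1, n):
            shared = leafsets[i] & leafsets[j]
            cells[i][j] = len(shared)
            cells[j][i] = (
                partition_metric(trees[i], trees[j]) if len(shared) >= 4 else None
            )
    return pd.DataFrame(cells, index=labels, columns=labels)
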