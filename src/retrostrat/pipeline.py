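"""End-to-end curation and training drivers shared by the CLI and tests."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from retrostrat.abstraction import (
    CuratedDataset,
    HigherLevelRoute,
    build_higher_level_route,
    concrete_route,
    curate_dataset,
)
from retrostrat.chem import (
    MappedReaction,
    ReactionParseError,
    RecordSkip,
    parse_mapped_reaction,
    read_reaction_records,
    validate_mapping,
)
from retrostrat.relevance import (
    TemplateClassifier,
    TrainConfig,
    split_dataset,
    top_k_accuracy,
    train_classifier,
)
from retrostrat.routes import (
    ProvenanceError,
    Route,
    build_network,
    extract_routes,
    trace_provenance,
)
from retrostrat.templates import TemplateLibrary, consolidate_templates

log = logging.getLogger(__name__)


@dataclass
class CurationResult:
    routes: list[Route]
    hl_routes: list[HigherLevelRoute]
    dataset: CuratedDataset
    skipped_records: int = 0
    skipped_routes: int = 0
    #: per-route (document, target, depth, n_reactions, hl_depth, hl_n_reactions)
    stats: list[dict] = field(default_factory=list)


def parse_corpus(path_or_records, multiproduct: str = "largest"):
    """Group validated reactions per document; count skipped records."""
    if isinstance(path_or_records, (str, bytes)) or hasattr(path_or_records, "__fspath__"):
        records = read_reaction_records(path_or_records)
    else:
        records = path_or_records
    by_doc: dict[str, list[MappedReaction]] = {}
    skipped = 0
    for document_id, record_id, smiles in records:
        try:
            rxn = parse_mapped_reaction(smiles, document_id, record_id, multiproduct)
        except (ReactionParseError, RecordSkip) as exc:
            log.warning("skipping record: %s", exc)
            skipped += 1
            continue
        report = validate_mapping(rxn)
        if not report.ok:
            log.warning("skipping %s: %s", record_id, "; ".join(report.entries()))
            skipped += 1
            continue
        by_doc.setdefault(document_id, []).append(rxn)
    return by_doc, skipped


def curate(
    path_or_records,
    space: str = "higher",
    max_depth: int = 10,
    exclusions=None,
) -> CurationResult:
    """Mine routes and build the curated dataset in one space.

    ``space='higher'`` abstracts leaving substructures and removes
    tactical steps; ``space='original'`` keeps concrete molecules and
    every step.
    """
    by_doc, skipped = parse_corpus(path_or_records)
    routes: list[Route] = []
    processed: list[HigherLevelRoute] = []
    stats = []
    skipped_routes = 0
    for document_id in sorted(by_doc):
        net = build_network(by_doc[document_id], document_id)
        for route in extract_routes(net, max_depth=max_depth):
            try:
                prov = trace_provenance(route)
                if space == "higher":
                    processed_route = build_higher_level_route(route, prov)
                else:
                    processed_route = concrete_route(route, prov)
            except ProvenanceError as exc:
                log.warning("excluding route: %s", exc)
                skipped_routes += 1
                continue
            routes.append(route)
            processed.append(processed_route)
            stats.append(
                {
                    "document_id": document_id,
                    "target": route.target,
                    "depth": route.depth,
                    "n_reactions": route.n_reactions,
                    "hl_depth": processed_route.depth,
                    "hl_n_reactions": processed_route.n_reactions,
                }
            )
    dataset = curate_dataset(processed, exclusions)
    return CurationResult(
        routes=routes,
        hl_routes=processed,
        dataset=dataset,
        skipped_records=skipped,
        skipped_routes=skipped_routes,
        stats=stats,
    )


@dataclass
class TrainResult:
    library: TemplateLibrary
    classifier: TemplateClassifier
    report_pessimistic: object
    report_optimistic: object


def train_pipeline(
    dataset: CuratedDataset,
    seed: int = 0,
    radius: int = 1,
    k_list: tuple[int, ...] = (1, 3, 5, 10, 25, 50),
    config: TrainConfig | None = None,
) -> TrainResult:
    """Consolidate templates, split, train, and evaluate both conventions."""
    library = consolidate_templates(dataset.entries, radius=radius)
    train, valid, test = split_dataset(dataset, seed=seed)
    config = config or TrainConfig(seed=seed)
    config.seed = seed
    clf = train_classifier(train, valid, library, config)
    rep_p = top_k_accuracy(clf, test, k_list, pessimistic=True)
    rep_o = top_k_accuracy(clf, test, k_list, pessimistic=False)
    return TrainResult(
        library=library,
        classifier=clf,
        report_pessimistic=rep_p,
        report_optimistic=rep_o,
    )
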