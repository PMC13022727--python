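"""Template-relevance classifier and pessimistic top-k evaluation.

A feedforward network maps a product's circular count fingerprint to a
probability over consolidated templates.  Marker pseudo-atoms are hashed
through a custom atom invariant that includes the isotope-coded marker
class, so electrophilic and nucleophilic attachment points produce
distinct substructure environments.

Top-k accuracy asks whether the literature-recorded precursor set is
among the k highest-ranked precursor proposals.  Because one template can
emit several precursor sets, the *pessimistic* convention ranks the
recorded set last within the block of proposals generated by its
template; the optimistic rank is its actual position.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.neural_network import MLPClassifier

from retrostrat.abstraction import CuratedDataset, DatasetEntry
from retrostrat.templates import RetroTemplate, TemplateLibrary, apply_template


@dataclass
class FingerprintConfig:
    radius: int = 2
    size: int = 2048


def _atom_invariants(mol: Chem.Mol) -> list[int]:
    out = []
    for a in mol.GetAtoms():
        key = (
            a.GetAtomicNum(),
            a.GetIsotope(),  # carries the marker class and multiplicity
            a.GetFormalCharge(),
            a.GetDegree(),
            a.GetTotalNumHs(),
            a.GetIsAromatic(),
            a.IsInRing(),
        )
        out.append(hash(key) & 0xFFFFFFFF)
    return out


def fingerprint(mol: Chem.Mol, config: FingerprintConfig | None = None) -> np.ndarray:
    """Marker-aware Morgan count fingerprint of one product molecule."""
    config = config or FingerprintConfig()
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius, fpSize=config.size
    )
    fp = gen.GetCountFingerprint(mol, customAtomInvariants=_atom_invariants(mol))
    vec = np.zeros(config.size, dtype=np.float32)
    for idx, count in fp.GetNonzeroElements().items():
        vec[idx] = count
    return vec


def split_dataset(
    ds: CuratedDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[DatasetEntry], list[DatasetEntry], list[DatasetEntry]]:
    """Random train/validation/test split over unique pairs."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(ds) < 10:
        raise ValueError("dataset too small to split")
    rng = np.random.RandomState(seed)
    order = rng.permutation(len(ds.entries))
    n_train = int(round(fractions[0] * len(order)))
    n_valid = int(round(fractions[1] * len(order)))
    train = [ds.entries[i] for i in order[:n_train]]
    valid = [ds.entries[i] for i in order[n_train : n_train + n_valid]]
    test = [ds.entries[i] for i in order[n_train + n_valid :]]
    return train, valid, test


@dataclass
class TrainConfig:
    hidden_size: int = 512
    max_epochs: int = 60
    learning_rate: float = 1e-3
    early_stopping: bool = True
    seed: int = 0
    fingerprint: FingerprintConfig = field(default_factory=FingerprintConfig)


@dataclass
class TemplateClassifier:
    """Fingerprint -> template scores, with the library it indexes into."""

    model: MLPClassifier
    library: TemplateLibrary
    template_ids: list[str]  # class index -> template id
    config: TrainConfig
    validation_top1: float = 0.0

    def templates(self) -> list[RetroTemplate]:
        return [self.library.templates[tid] for tid in self.template_ids]

    def scores(self, product: Chem.Mol) -> np.ndarray:
        """Probability per template (vocabulary order), summing to 1."""
        x = fingerprint(product, self.config.fingerprint)[None, :]
        proba = self.model.predict_proba(x)[0]
        out = np.zeros(len(self.template_ids))
        for cls_idx, cls in enumerate(self.model.classes_):
            out[cls] = proba[cls_idx]
        return out

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "TemplateClassifier":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _features_labels(entries, library: TemplateLibrary, template_index, fp_config):
    xs, ys, kept = [], [], []
    for e in entries:
        tid = library.assignment.get(e.key)
        if tid is None:
            continue
        xs.append(fingerprint(e.example.product, fp_config))
        ys.append(template_index[tid])
        kept.append(e)
    return np.array(xs), np.array(ys), kept


def train_classifier(
    train: list[DatasetEntry],
    valid: list[DatasetEntry],
    library: TemplateLibrary,
    config: TrainConfig | None = None,
) -> TemplateClassifier:
    """Fit the relevance network on consolidated template labels."""
    config = config or TrainConfig()
    template_ids = [t.template_id for t in library.sorted_templates()]
    template_index = {tid: i for i, tid in enumerate(template_ids)}
    x_train, y_train, _ = _features_labels(train, library, template_index, config.fingerprint)
    x_valid, y_valid, _ = _features_labels(valid, library, template_index, config.fingerprint)
    n_classes = len(set(y_train))
    model = MLPClassifier(
        hidden_layer_sizes=(config.hidden_size,),
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        max_iter=config.max_epochs,
        # the internal validation split starves tiny training sets
        early_stopping=config.early_stopping and len(x_train) >= 500 and n_classes > 1,
        n_iter_no_change=8,
        validation_fraction=0.1,
        random_state=config.seed,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x_train, y_train)
    clf = TemplateClassifier(
        model=model, library=library, template_ids=template_ids, config=config
    )
    if len(x_valid):
        clf.validation_top1 = float(np.mean(model.predict(x_valid) == y_valid))
    return clf


def rank_precursors(
    clf: TemplateClassifier, product: Chem.Mol, k: int
) -> list[tuple[RetroTemplate, tuple[str, ...], float]]:
    """Precursor proposals from the top-k templates, highest score first.

    Within the top-k templates (ties broken by template id), each
    applicable template contributes its distinct precursor sets in
    canonical-string order; non-applicable templates are skipped.
    """
    if k <= 0:
        return []
    scores = clf.scores(product)
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], clf.template_ids[i]))
    out = []
    for idx in order[:k]:
        template = clf.library.templates[clf.template_ids[idx]]
        for smis, _ in apply_template(template, product):
            out.append((template, smis, float(scores[idx])))
    return out


@dataclass
class EvalReport:
    """Per-k accuracies (percent) over one test set."""

    k_values: list[int]
    accuracy: dict[int, float]  # percent
    n_products: int
    pessimistic: bool

    def table(self) -> str:
        lines = ["  k   top-k accuracy (%)"]
        for k in self.k_values:
            lines.append(f"{k:3d}   {self.accuracy[k]:6.1f}")
        return "\n".join(lines)


def _rank_of_truth(
    clf: TemplateClassifier, entry: DatasetEntry, max_k: int, pessimistic: bool
) -> int | None:
    """1-based rank of the recorded precursor set, or None if not found."""
    scores = clf.scores(entry.example.product)
    order = sorted(
        range(len(scores)), key=lambda i: (-scores[i], clf.template_ids[i])
    )
    position = 0
    for idx in order[:max_k]:
        template = clf.library.templates[clf.template_ids[idx]]
        results = apply_template(template, entry.example.product)
        block = [smis for smis, _ in results]
        if entry.reactants in block:
            if pessimistic:
                return position + len(block)
            return position + 1 + block.index(entry.reactants)
        position += len(block)
    return None


def top_k_accuracy(
    clf: TemplateClassifier,
    test: list[DatasetEntry],
    k_list: tuple[int, ...] = (1, 3, 5, 10, 25, 50),
    pessimistic: bool = True,
) -> EvalReport:
    """Fraction of test products whose recorded precursors rank within k."""
    k_list = sorted(k_list)
    max_templates = max(k_list)
    hits = {k: 0 for k in k_list}
    for entry in test:
        rank = _rank_of_truth(clf, entry, max_templates, pessimistic)
        if rank is None:
            continue
        for k in k_list:
            if rank <= k:
                hits[k] += 1
    n = max(1, len(test))
    return EvalReport(
        k_values=list(k_list),
        accuracy={k: 100.0 * hits[k] / n for k in k_list},
        n_products=len(test),
        pessimistic=pessimistic,
    )


def write_report(report: EvalReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "k": report.k_values,
                "accuracy_percent": {str(k): report.accuracy[k] for k in report.k_values},
                "n_products": report.n_products,
                "pessimistic": report.pessimistic,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
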