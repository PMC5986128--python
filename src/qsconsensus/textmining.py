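"""Oligomeric-state extraction from article full text.

A primary publication usually states the oligomeric state of the structure
it reports, often alongside the solution experiment that established it
("the protein elutes as a dimer on size-exclusion chromatography").  The
pipeline extracts that statement in five stages:

1. sentence splitting with abbreviation guards,
2. a first keyword filter keeping sentences that mention an oligomeric
   state (monomer, dimer, ..., dodecamer, with morphological variants),
3. a trained sentence classifier that discards misleading mentions
   (descriptions of the asymmetric unit, of other proteins, of crystal
   packing) and keeps quaternary-structure-relevant sentences,
4. a second keyword filter requiring experimental-evidence phrases,
5. a majority tally of the surviving oligomer keywords; the strict-majority
   winner becomes the predicted oligomer order.

The classifier featurizes sentences with tf-idf weights,

    tf-idf(n, s) = tf(n, s) * ln(N / df(n)),

where tf(n, s) is the count of word n in sentence s, df(n) the number of
sentences containing n, and N the corpus size, hashed into 2**18 buckets
with MurmurHash3 (signed feature hashing).  The default classifier is an
RBF-kernel SVM; a boosted logistic-regression alternative is provided.  The
method predicts only the oligomer order — symmetry is not extractable from
text reliably — so its annotations never carry symmetry and compare by total
subunit count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.utils import murmurhash3_32
from sklearn.utils.validation import check_is_fitted

from .annotations import QSAnnotation, Source, Status, Stoichiometry

__all__ = [
    "SentenceRecord",
    "ClassifierConfig",
    "MetricSet",
    "split_sentences",
    "keyword_filter",
    "preprocess",
    "tfidf_weights",
    "hash_features",
    "HashedTfidfVectorizer",
    "SentenceClassifier",
    "train_classifier",
    "evaluate_classifier",
    "extract_stoichiometry",
    "load_oligomer_keywords",
    "load_evidence_keywords",
    "REPORTED_SVM_SIGMA",
    "REPORTED_SVM_COST",
    "REPORTED_BLR_ITERATIONS",
]

#: Hyperparameters reported for the original (non-deposited) 11,000-sentence
#: corpus, kept as provenance metadata.  The caret-style RBF "sigma" does not
#: map one-to-one onto scikit-learn's gamma, so the estimator exposes gamma
#: directly instead of silently reinterpreting sigma.
REPORTED_SVM_SIGMA = 0.013
REPORTED_SVM_COST = 4.0
REPORTED_BLR_ITERATIONS = 101

_ABBREVIATIONS = (
    "fig", "figs", "eq", "eqs", "ref", "refs", "et al", "al", "e.g", "i.e",
    "cf", "ca", "approx", "resp", "vs", "no", "dr", "prof", "inc", "spp",
)
_ABBREV_RE = re.compile(
    r"(?:^|[\s(])(?:" + "|".join(a.replace(".", r"\.") for a in _ABBREVIATIONS) + r")\.$",
    re.IGNORECASE,
)
_BOUNDARY_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9(])")


@dataclass
class SentenceRecord:
    """One sentence with its normalized tokens and optional class label."""

    text: str
    tokens: list[str] = field(default_factory=list)
    label: str | None = None  # "positive" | "negative" | None

    def __post_init__(self) -> None:
        if not self.tokens:
            self.tokens = preprocess(self.text)


@dataclass
class ClassifierConfig:
    algorithm: str = "svm"           # "svm" | "blr"
    gamma: float | str = "scale"     # RBF width (SVM)
    cost: float = REPORTED_SVM_COST  # penalty C (SVM)
    iterations: int = REPORTED_BLR_ITERATIONS  # boosting rounds (BLR)
    cv_folds: int = 0                # >0 enables grid-search CV on the train split
    split: float = 0.8               # train fraction

    def __post_init__(self) -> None:
        if self.algorithm not in ("svm", "blr"):
            raise ValueError("algorithm must be 'svm' or 'blr'")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    kappa: float
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    mcc: float


def split_sentences(full_text: str) -> list[SentenceRecord]:
    """Split article text into sentences at terminal punctuation.

    Boundaries are sentence-final ``.!?`` followed by whitespace and an
    uppercase/digit/parenthesis start, guarded against common abbreviations
    ("Fig.", "et al.", "e.g."...).  The concatenation of the returned
    sentences reconstructs the input up to the whitespace consumed at
    boundaries.
    """
    if not full_text or not full_text.strip():
        raise ValueError("empty article text")
    pieces: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(full_text):
        candidate = full_text[start : m.start() + 1]
        if _ABBREV_RE.search(candidate.rstrip()):
            continue  # boundary inside an abbreviation: keep scanning
        pieces.append(candidate)
        start = m.end()
    tail = full_text[start:]
    if tail.strip():
        pieces.append(tail)
    return [SentenceRecord(text=p.strip()) for p in pieces if p.strip()]


def _variant_pattern(keyword: str) -> re.Pattern:
    # whole word with optional homo-/hetero- prefix and -s/-ic suffix
    return re.compile(
        rf"\b(?:homo|hetero)?[-\s]?{re.escape(keyword)}(?:s|ic)?\b", re.IGNORECASE
    )


def keyword_filter(
    sentences: Sequence[SentenceRecord], keywords: Sequence[str]
) -> list[SentenceRecord]:
    """Keep sentences containing any keyword (case-insensitive, whole-word,
    with morphological variants: dimer, dimers, dimeric, homodimer...).
    Multi-word keywords match as phrases in the normalized sentence.
    Preserves order; adding keywords can only grow the retained set."""
    if not keywords:
        raise ValueError("keyword list is empty")
    single = [_variant_pattern(k) for k in keywords if " " not in k]
    phrases = [k.lower() for k in keywords if " " in k]
    kept = []
    for s in sentences:
        normalized = " ".join(s.tokens)
        if any(p.search(s.text) for p in single) or any(
            ph in normalized for ph in phrases
        ):
            kept.append(s)
    return kept


_PUNCT_RE = re.compile(r"[^a-z0-9 ]")


def preprocess(sentence: str) -> list[str]:
    """Lowercase, strip punctuation (hyphens included), collapse whitespace,
    split on spaces."""
    if not sentence:
        raise ValueError("empty sentence")
    lowered = sentence.lower()
    cleaned = _PUNCT_RE.sub(" ", lowered)
    return cleaned.split()


def tfidf_weights(
    corpus: Sequence[Sequence[str]],
) -> tuple["TfIdfModel", list[dict[str, float]]]:
    """Per-sentence tf-idf weights: tf(n, s) * ln(N / df(n)), natural log.

    A token occurring in every sentence weighs exactly 0; all weights are
    non-negative.
    """
    if not corpus:
        raise ValueError("empty corpus")
    N = len(corpus)
    df: dict[str, int] = {}
    for tokens in corpus:
        for token in set(tokens):
            df[token] = df.get(token, 0) + 1
    model = TfIdfModel(doc_count=N, df=df)
    vectors = [model.weigh(tokens) for tokens in corpus]
    return model, vectors


@dataclass
class TfIdfModel:
    """Document frequencies learned from a sentence corpus."""

    doc_count: int
    df: dict[str, int]

    def __post_init__(self) -> None:
        for token, d in self.df.items():
            if not (1 <= d <= self.doc_count):
                raise ValueError(f"df({token!r}) = {d} outside [1, {self.doc_count}]")

    def idf(self, token: str) -> float:
        d = self.df.get(token)
        if d is None:
            return 0.0  # unseen token carries no weight at transform time
        return float(np.log(self.doc_count / d))

    def weigh(self, tokens: Sequence[str]) -> dict[str, float]:
        tf: dict[str, int] = {}
        for token in tokens:
            tf[token] = tf.get(token, 0) + 1
        return {t: c * self.idf(t) for t, c in tf.items()}


def hash_features(
    weights: Mapping[str, float],
    dim: int = 2**18,
    signed: bool = True,
    seed: int = 0,
) -> sp.csr_matrix:
    """Hash a token->weight map into a sparse vector of ``dim`` buckets.

    bucket = MurmurHash3(token) mod dim; colliding tokens' weights sum.
    With ``signed`` (default) a second hash bit flips the sign so collisions
    cancel in expectation; unsigned hashing conserves the total weight.
    """
    if dim <= 0 or dim & (dim - 1):
        raise ValueError("dim must be a power of two")
    vec = np.zeros(dim)
    for token, w in weights.items():
        h = murmurhash3_32(token, seed=seed, positive=True)
        bucket = h % dim
        sign = 1.0
        if signed:
            sign = 1.0 if murmurhash3_32(token, seed=seed + 1, positive=True) & 1 else -1.0
        vec[bucket] += sign * w
    return sp.csr_matrix(vec)


class HashedTfidfVectorizer(BaseEstimator, TransformerMixin):
    """Tf-idf weighting followed by MurmurHash3 feature hashing.

    Unlike stock tf-idf vectorizers this uses the plain ``tf * ln(N/df)``
    form with no smoothing and no normalization, matching the weighting the
    rest of the module documents, and hashes tokens instead of keeping a
    vocabulary so the feature space is fixed at ``2**n_bits``.
    """

    def __init__(self, n_bits: int = 18, signed: bool = True, hash_seed: int = 0):
        self.n_bits = n_bits
        self.signed = signed
        self.hash_seed = hash_seed

    def fit(self, X: Sequence[str], y=None) -> "HashedTfidfVectorizer":
        corpus = [preprocess(s) if isinstance(s, str) else list(s) for s in X]
        self.model_, _ = tfidf_weights(corpus)
        return self

    def transform(self, X: Sequence[str]) -> sp.csr_matrix:
        check_is_fitted(self, "model_")
        dim = 2**self.n_bits
        rows = []
        for s in X:
            tokens = preprocess(s) if isinstance(s, str) else list(s)
            rows.append(
                hash_features(
                    self.model_.weigh(tokens), dim, self.signed, self.hash_seed
                )
            )
        return sp.vstack(rows).tocsr()


class SentenceClassifier(BaseEstimator, ClassifierMixin):
    """Quaternary-structure sentence relevance classifier.

    A scikit-learn estimator: ``fit(sentences, labels)`` then
    ``predict``/``predict_proba`` on raw sentence strings.  Features are
    hashed tf-idf vectors; the model is an RBF-kernel SVM
    (``algorithm='svm'``, C = ``cost``) or stagewise boosted logistic
    regression (``algorithm='blr'``, ``iterations`` rounds).

    Parameters mirror :class:`ClassifierConfig`; ``gamma`` is scikit-learn's
    RBF coefficient (default ``'scale'``).
    """

    def __init__(
        self,
        algorithm: str = "svm",
        gamma: float | str = "scale",
        cost: float = REPORTED_SVM_COST,
        iterations: int = REPORTED_BLR_ITERATIONS,
        n_bits: int = 18,
        random_state: int | None = None,
    ):
        self.algorithm = algorithm
        self.gamma = gamma
        self.cost = cost
        self.iterations = iterations
        self.n_bits = n_bits
        self.random_state = random_state

    def _make_model(self):
        if self.algorithm == "svm":
            return SVC(
                kernel="rbf",
                gamma=self.gamma,
                C=self.cost,
                random_state=self.random_state,
            )
        if self.algorithm == "blr":
            return GradientBoostingClassifier(
                n_estimators=self.iterations, random_state=self.random_state
            )
        raise ValueError("algorithm must be 'svm' or 'blr'")

    def fit(self, X: Sequence[str], y: Sequence[str]) -> "SentenceClassifier":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training corpus must contain both classes")
        self.vectorizer_ = HashedTfidfVectorizer(n_bits=self.n_bits)
        features = self.vectorizer_.fit(X).transform(X)
        self.model_ = self._make_model().fit(features, y)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X: Sequence[str]) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(self.vectorizer_.transform(X))

    def decision_scores(self, X: Sequence[str]) -> np.ndarray:
        """Score increasing with positive-class confidence, for ROC analysis."""
        check_is_fitted(self, "model_")
        features = self.vectorizer_.transform(X)
        if hasattr(self.model_, "decision_function"):
            scores = np.asarray(self.model_.decision_function(features))
            # decision_function scores classes_[1]; flip if that is negative
            return scores if self.classes_[1] == "positive" else -scores
        proba = self.model_.predict_proba(features)
        pos_idx = int(np.argmax(self.classes_ == "positive"))
        return proba[:, pos_idx]


def train_classifier(
    corpus: Sequence[SentenceRecord],
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> tuple[SentenceClassifier, MetricSet]:
    """Train on a labeled corpus with a stratified train/test split.

    The corpus is split ``config.split`` / ``1 - split`` (default 80/20,
    stratified); with ``cv_folds > 0`` a grid search over gamma and cost is
    run on the training portion.  Returns the fitted classifier and the
    held-out :class:`MetricSet`.
    """
    config = config or ClassifierConfig()
    texts = [s.text for s in corpus]
    labels = [s.label for s in corpus]
    if any(l is None for l in labels):
        raise ValueError("all training sentences must be labeled")
    if len(set(labels)) < 2:
        raise ValueError("training corpus must contain both classes")
    X_train, X_test, y_train, y_test = train_test_split(
        texts,
        labels,
        train_size=config.split,
        stratify=labels,
        random_state=seed,
    )
    clf = SentenceClassifier(
        algorithm=config.algorithm,
        gamma=config.gamma,
        cost=config.cost,
        iterations=config.iterations,
        random_state=seed,
    )
    if config.cv_folds > 0 and config.algorithm == "svm":
        from sklearn.model_selection import GridSearchCV

        grid = GridSearchCV(
            clf,
            {"gamma": ["scale", 0.01, 0.1], "cost": [1.0, 4.0, 16.0]},
            cv=config.cv_folds,
            n_jobs=1,
        )
        grid.fit(X_train, y_train)
        clf = grid.best_estimator_
    else:
        clf.fit(X_train, y_train)
    predictions = clf.predict(X_test)
    scores = clf.decision_scores(X_test)
    metrics = evaluate_classifier(predictions, y_test, scores)
    return clf, metrics


def evaluate_classifier(
    predictions: Sequence[str],
    truth: Sequence[str],
    scores: Sequence[float] | None = None,
    positive_label: str = "positive",
) -> MetricSet:
    """All nine confusion-matrix metrics (AUC from scores when given)."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.size == 0 or predictions.shape != truth.shape:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    pos_pred = predictions == positive_label
    pos_true = truth == positive_label
    tp = int(np.sum(pos_pred & pos_true))
    tn = int(np.sum(~pos_pred & ~pos_true))
    fp = int(np.sum(pos_pred & ~pos_true))
    fn = int(np.sum(~pos_pred & pos_true))
    n = tp + tn + fp + fn

    def safe(num: float, den: float) -> float:
        return num / den if den else 0.0

    sensitivity = safe(tp, tp + fn)
    specificity = safe(tn, tn + fp)
    ppv = safe(tp, tp + fp)
    npv = safe(tn, tn + fn)
    if scores is not None and len(set(truth.tolist())) == 2:
        auc = float(roc_auc_score(pos_true.astype(int), np.asarray(scores)))
    else:
        auc = 0.5
    return MetricSet(
        accuracy=safe(tp + tn, n),
        kappa=float(cohen_kappa_score(truth, predictions)) if n else 0.0,
        auc=auc,
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=ppv,
        npv=npv,
        f1=safe(2 * tp, 2 * tp + fp + fn),
        mcc=float(matthews_corrcoef(truth, predictions)) if n else 0.0,
    )


def _load_keyword_file(name: str) -> list[str]:
    text = resources.files("qsconsensus.data").joinpath(name).read_text()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[0])
    return out


def load_oligomer_keywords() -> dict[str, int]:
    """Default oligomer keyword -> subunit count map (monomer..dodecamer)."""
    text = resources.files("qsconsensus.data").joinpath("oligomer_keywords.txt").read_text()
    mapping: dict[str, int] = {}
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            keyword, order = line.split("\t")
            mapping[keyword] = int(order)
    return mapping


def load_evidence_keywords() -> list[str]:
    """Default experimental-evidence phrase list."""
    return _load_keyword_file("evidence_keywords.txt")


def extract_stoichiometry(
    article_text: str | None,
    model: SentenceClassifier | None,
    oligo_keywords: Mapping[str, int] | None = None,
    evidence_keywords: Sequence[str] | None = None,
    evidence_scope: str = "sentence",
) -> QSAnnotation:
    """Predict the oligomer order stated in an article's full text.

    Runs split -> oligomer-keyword filter -> classifier (keep positive) ->
    evidence filter -> strict-majority tally of oligomer keywords.  The
    winner maps to a total subunit count (dimer -> 2, ...), reported as an
    order-only annotation with source TM and no symmetry.  No surviving
    sentence, or a tied tally, yields ``inconclusive``; a missing article
    yields ``not_available``.  ``evidence_scope='article'`` relaxes the
    evidence filter to require an evidence phrase anywhere in the article
    rather than in the same sentence.
    """
    if article_text is None or not article_text.strip():
        return QSAnnotation.not_available(Source.TM)
    if evidence_scope not in ("sentence", "article"):
        raise ValueError("evidence_scope must be 'sentence' or 'article'")
    oligo = dict(oligo_keywords) if oligo_keywords else load_oligomer_keywords()
    evidence = list(evidence_keywords) if evidence_keywords else load_evidence_keywords()

    sentences = split_sentences(article_text)
    candidates = keyword_filter(sentences, list(oligo))
    if model is not None and candidates:
        verdicts = model.predict([s.text for s in candidates])
        candidates = [s for s, v in zip(candidates, verdicts) if v == "positive"]
    if evidence_scope == "sentence":
        survivors = keyword_filter(candidates, evidence)
    else:
        has_evidence = bool(keyword_filter(sentences, evidence))
        survivors = candidates if has_evidence else []
    if not survivors:
        return QSAnnotation.inconclusive(Source.TM)

    tally: dict[int, int] = {}
    for s in survivors:
        for keyword, order in oligo.items():
            if _variant_pattern(keyword).search(s.text):
                tally[order] = tally.get(order, 0) + 1
    if not tally:
        return QSAnnotation.inconclusive(Source.TM)
    total = sum(tally.values())
    order, votes = max(tally.items(), key=lambda kv: kv[1])
    if 2 * votes <= total:  # strict majority required; ties are inconclusive
        return QSAnnotation.inconclusive(Source.TM)
    return QSAnnotation(
        stoichiometry=Stoichiometry({"A": order}),
        source=Source.TM,
        order_only=True,
    )
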