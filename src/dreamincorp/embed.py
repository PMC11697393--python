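"""Text embedding behind a pluggable backend.

Two backends are exposed through one interface:

``hashed_bow_test``
    A deterministic hashed bag-of-words embedder (signed feature
    hashing with log(1+count) term weights, L2-normalized). It carries
    no semantics beyond token overlap — it exists so that the whole
    scoring pipeline is exercisable and testable with no model
    download. Texts with disjoint token sets have expected cosine 0;
    expected cosine grows monotonically with shared-token fraction.

``transformer_external``
    A contextual sentence encoder (e.g. a German BERT) reached through
    the ``transformers`` library, mean- or first-token-pooled. Weights
    are never bundled; if the library or model is unavailable the call
    raises :class:`BackendError` rather than silently degrading.

An optional summarization stage sits in front of whole-text embedding;
its ``identity`` mode (the default) passes text through unchanged, the
``external_model`` mode delegates to an abstractive summarizer under the
same availability contract.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass

import numpy as np

from .errors import BackendError, EmptyTextError, UndefinedSimilarityError


@dataclass(frozen=True)
class EmbeddingVector:
    values: np.ndarray
    backend_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise UndefinedSimilarityError("embedding has non-finite entries")

    @property
    def dimension(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class EmbedderSpec:
    """Backend selection; exactly one backend per spec.

    ``dimension`` and ``seed`` configure the test backend (the seed
    salts the token hash); ``model_name`` and ``pooling`` configure the
    external backend.
    """

    backend: str = "hashed_bow_test"
    pooling: str = "mean_tokens"
    model_name: str | None = None
    dimension: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("hashed_bow_test", "transformer_external"):
            raise BackendError(f"unknown embedding backend {self.backend!r}")
        if self.pooling not in ("mean_tokens", "first_token"):
            raise BackendError(f"unknown pooling {self.pooling!r}")
        if self.dimension < 1:
            raise BackendError("dimension must be positive")

    @property
    def backend_id(self) -> str:
        if self.backend == "hashed_bow_test":
            return f"hashed_bow_test(d={self.dimension},seed={self.seed})"
        return f"transformer_external({self.model_name},{self.pooling})"


@dataclass(frozen=True)
class SummarizerSpec:
    mode: str = "identity"
    model_name: str | None = None
    max_length: int = 128

    def __post_init__(self) -> None:
        if self.mode not in ("identity", "external_model"):
            raise BackendError(f"unknown summarizer mode {self.mode!r}")
        if self.max_length < 1:
            raise BackendError("max_length must be positive")


def summarize(text: str, spec: SummarizerSpec | None = None) -> str:
    """Optional abstractive summarization before whole-text embedding."""
    if spec is None:
        spec = SummarizerSpec()
    if not text or not text.strip():
        raise EmptyTextError("cannot summarize empty text")
    if spec.mode == "identity":
        return text
    try:
        import transformers  # noqa: F401
    except ImportError:
        raise BackendError(
            "summarizer backend 'external_model' requires the transformers "
            "library, which is not installed; use mode='identity' instead"
        ) from None
    raise BackendError(
        "external summarization model is not configured in this environment; "
        "use mode='identity' instead"
    )


_TOKEN = re.compile(r"\w+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens (punctuation dropped)."""
    return _TOKEN.findall(text.lower())


class HashedBowEmbedder:
    """Signed feature-hashing bag-of-words embedder (test backend).

    Each distinct token is hashed (BLAKE2b salted with the spec seed)
    into one of ``d`` bins with a ±1 sign and contributes
    ``log(1+count)`` weight; the vector is L2-normalized so cosine
    reduces to a dot product. Fully deterministic given spec and text.
    """

    def __init__(self, spec: EmbedderSpec):
        if spec.backend != "hashed_bow_test":
            raise BackendError("HashedBowEmbedder requires backend='hashed_bow_test'")
        self.spec = spec
        self._salt = str(spec.seed).encode("utf-8")
        self._slots: dict[str, tuple[int, int]] = {}

    def _slot(self, token: str) -> tuple[int, int]:
        cached = self._slots.get(token)
        if cached is None:
            digest = hashlib.blake2b(
                token.encode("utf-8"), key=self._salt, digest_size=9
            ).digest()
            idx = int.from_bytes(digest[:8], "little") % self.spec.dimension
            sign = 1 if digest[8] & 1 else -1
            cached = (idx, sign)
            self._slots[token] = cached
        return cached

    def embed(self, text: str) -> EmbeddingVector:
        if not text or not text.strip():
            raise EmptyTextError("cannot embed empty text")
        tokens = tokenize(text)
        if not tokens:
            raise EmptyTextError("text contains no word tokens")
        counts: dict[str, int] = {}
        for t in tokens:
            counts[t] = counts.get(t, 0) + 1
        vec = np.zeros(self.spec.dimension)
        for token, count in counts.items():
            idx, sign = self._slot(token)
            vec[idx] += sign * np.log1p(count)
        norm = np.linalg.norm(vec)
        if norm == 0.0:
            # only possible through exact sign cancellation
            raise UndefinedSimilarityError(
                "hashed embedding collapsed to the zero vector"
            )
        return EmbeddingVector(values=vec / norm, backend_id=self.spec.backend_id)


class TransformerEmbedder:
    """Contextual-encoder backend; probes for transformers at call time."""

    def __init__(self, spec: EmbedderSpec):
        if spec.backend != "transformer_external":
            raise BackendError("TransformerEmbedder requires backend='transformer_external'")
        if not spec.model_name:
            raise BackendError("transformer_external backend requires model_name")
        self.spec = spec

    def embed(self, text: str) -> EmbeddingVector:
        if not text or not text.strip():
            raise EmptyTextError("cannot embed empty text")
        try:
            import torch  # noqa: F401
            import transformers  # noqa: F401
        except ImportError:
            raise BackendError(
                "transformer_external backend requires torch + transformers, "
                "which are not installed; use the hashed_bow_test backend for "
                "offline runs"
            ) from None
        from transformers import AutoModel, AutoTokenizer  # pragma: no cover

        tok = AutoTokenizer.from_pretrained(self.spec.model_name)  # pragma: no cover
        model = AutoModel.from_pretrained(self.spec.model_name)  # pragma: no cover
        import torch as _t  # pragma: no cover

        with _t.no_grad():  # pragma: no cover
            enc = tok(text, return_tensors="pt", truncation=True)
            out = model(**enc).last_hidden_state[0]
            if self.spec.pooling == "first_token":
                v = out[0]
            else:
                v = out.mean(dim=0)
            v = v / v.norm()
            return EmbeddingVector(
                values=v.numpy().astype(float), backend_id=self.spec.backend_id
            )


def make_embedder(spec: EmbedderSpec | None = None):
    """Instantiate the backend named by the spec."""
    if spec is None:
        spec = EmbedderSpec()
    if spec.backend == "hashed_bow_test":
        return HashedBowEmbedder(spec)
    return TransformerEmbedder(spec)


def embed_text(text: str, spec: EmbedderSpec | None = None) -> EmbeddingVector:
    """One-shot embedding; for bulk work keep a :func:`make_embedder`
    instance, which caches token hash slots across calls."""
    return make_embedder(spec).embed(text)
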