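"""Optional adapters for external pretrained models (lazy imports).

These back the same contracts as the toy components — an autoregressive
token-probability backend and a sentence embedder — with locally cached
pretrained models.  They require the ``external`` extra (transformers, torch,
sentence-transformers) and a model download, so nothing here is imported by
the default pipeline or the test suite; the scoring layer is proven
backend-agnostic with a recorded-reply stub instead.

With a cached GPT-2-class model, ``HuggingFaceCausalBackend`` supports the
worked sanity check for the conditional-surprisal convention: scoring
"The tailor lended an umbreller to an actor" against the target "The tailor
lends the actor the umbrella" should land near 5.45 (per-token mean), and the
less aligned "The tailor lended an book to an athlete" near 6.77 and strictly
higher.  Exact values depend on the tokenizer and context-joining convention,
so the check is tolerance-based (±0.25), not exact.
"""

from __future__ import annotations

from typing import Sequence

from .lm_backend import BackendDescriptor, ScoringError, TokenScore


class HuggingFaceCausalBackend:
    """Token log-probabilities from a local HuggingFace causal LM.

    Context and continuation are joined with a single space after the
    tokenizer's begin-of-sequence marker; only continuation tokens contribute
    scores.  The adapter owns its tokenization and reports its own token
    counts.
    """

    def __init__(self, model_name: str = "gpt2", device: str = "cpu"):
        import torch  # deferred: optional heavy dependency
        from transformers import AutoModelForCausalLM, AutoTokenizer

        self._torch = torch
        self.tokenizer = AutoTokenizer.from_pretrained(model_name)
        self.model = AutoModelForCausalLM.from_pretrained(model_name).to(device)
        self.model.eval()
        self.device = device
        self.descriptor = BackendDescriptor(
            name=model_name, vocabulary_size=None,
            tokenizer_policy="model tokenizer; BOS + context + ' ' + continuation",
        )

    def score(self, context: str, continuation: str) -> list[TokenScore]:
        torch = self._torch
        if not continuation.strip():
            raise ScoringError("empty continuation")
        bos = self.tokenizer.bos_token or ""
        prefix = f"{bos}{context}" if context else bos
        joined = f"{prefix} {continuation}" if context else f"{prefix}{continuation}"
        prefix_ids = self.tokenizer(prefix, return_tensors="pt").input_ids
        full_ids = self.tokenizer(joined, return_tensors="pt").input_ids
        n_prefix = prefix_ids.shape[1]
        with torch.no_grad():
            logits = self.model(full_ids.to(self.device)).logits
        logprobs = torch.log_softmax(logits, dim=-1)
        scores = []
        for pos in range(n_prefix, full_ids.shape[1]):
            token_id = full_ids[0, pos]
            lp = float(logprobs[0, pos - 1, token_id])
            scores.append(
                TokenScore(self.tokenizer.decode(token_id).strip() or "<tok>",
                           min(lp, 0.0))
            )
        if not scores:
            raise ScoringError("continuation produced no tokens")
        return scores


class SentenceTransformerEmbedder:
    """Dense sentence embeddings for the semantic-similarity control."""

    name = "sentence_transformer"

    def __init__(self, model_name: str = "sentence-transformers/all-MiniLM-L6-v2"):
        from sentence_transformers import SentenceTransformer  # deferred

        self.model = SentenceTransformer(model_name)

    def embed(self, text: str) -> "Sequence[float]":
        return self.model.encode([text])[0]


__all__ = ["HuggingFaceCausalBackend", "SentenceTransformerEmbedder"]
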