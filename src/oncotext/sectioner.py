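"""Assessment/plan extraction from oncologist notes.

The outcome-bearing content of an oncologist note lives in its
assessment/plan (A/P) section.  This module provides

* a rules-based token labeler — the first matched A/P header (from a
  configurable, case-insensitive header list) opens the section, which runs
  to the next recognized section header or the end of the note;
* :class:`RNNSectionTagger`, a small recurrent sequence tagger trained on
  rules-labeled notes and applied at inference, predicting an in/out tag per
  token conditioned on the tokens seen so far;
* :func:`extract_assessment_plan`, which returns the A/P text (falling back
  to the full note when no section is found, so no document is dropped).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .lexicons import AP_HEADERS, OTHER_SECTION_HEADERS

IN_AP = "in_ap"
OUT_AP = "out_ap"

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


@dataclass
class TokenizedNote:
    """Tokens with character offsets and per-token section tags."""

    text: str
    tokens: list  # (token_text, start_offset, end_offset)
    tags: list  # IN_AP | OUT_AP per token

    def ap_span_text(self) -> str:
        """Original text spanned by the in_ap tokens (empty if none)."""
        idx = [i for i, t in enumerate(self.tags) if t == IN_AP]
        if not idx:
            return ""
        start = self.tokens[idx[0]][1]
        end = self.tokens[idx[-1]][2]
        return self.text[start:end]


def tokenize(text: str):
    """Whitespace/punctuation tokenization with character offsets."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _header_pattern(headers) -> re.Pattern:
    alts = "|".join(re.escape(h) for h in sorted(headers, key=len, reverse=True))
    return re.compile(rf"(?<!\w)({alts})[ \t]*:", re.IGNORECASE)


def rules_label_sections(
    text: str,
    ap_headers=AP_HEADERS,
    section_headers=OTHER_SECTION_HEADERS,
) -> TokenizedNote:
    """Tag tokens from the first matched A/P header to the next recognized
    section header (or end of note) as in_ap; everything else out_ap."""
    tokens = tokenize(text)
    tags = [OUT_AP] * len(tokens)
    ap_match = _header_pattern(ap_headers).search(text)
    if ap_match is not None:
        start = ap_match.end()
        boundary = _header_pattern(tuple(ap_headers) + tuple(section_headers)).search(
            text, pos=start
        )
        end = boundary.start() if boundary is not None else len(text)
        for i, (_, a, b) in enumerate(tokens):
            if a >= start and b <= end:
                tags[i] = IN_AP
    return TokenizedNote(text=text, tokens=tokens, tags=tags)


class RNNSectionTagger(BaseEstimator):
    """Elman recurrent network tagging each note token as in/out of the A/P.

    Per-token prediction is conditioned on the running hidden state, so the
    tagger can latch "a section header was just seen" across arbitrary
    distances.  Training is deterministic for a fixed ``seed``.

    Parameters
    ----------
    embed_dim, hidden_dim : int
        Token embedding and recurrent state sizes.
    epochs, lr : training schedule (Adam).
    min_count : minimum token frequency for the vocabulary; rarer tokens map
        to the unknown index.
    """

    def __init__(self, embed_dim=16, hidden_dim=32, epochs=3, lr=0.02,
                 min_count=1, seed=0, clip=5.0):
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        self.epochs = epochs
        self.lr = lr
        self.min_count = min_count
        self.seed = seed
        self.clip = clip

    # -- vocabulary ---------------------------------------------------
    def _encode(self, token_texts):
        return np.array(
            [self.vocab_.get(t.lower(), 1) for t in token_texts], dtype=np.int64
        )

    def _build_vocab(self, tokenized_texts):
        counts: dict[str, int] = {}
        for toks in tokenized_texts:
            for t in toks:
                counts[t] = counts.get(t, 0) + 1
        vocab = {"<pad>": 0, "<unk>": 1}
        for t in sorted(counts):
            if counts[t] >= self.min_count:
                vocab[t] = len(vocab)
        return vocab

    # -- training -----------------------------------------------------
    def fit(self, texts, tag_sequences=None):
        """Fit on notes; ``tag_sequences`` defaults to rules-based labels.

        Each tag sequence holds 0 (out_ap) / 1 (in_ap) per token of the
        corresponding tokenized text.
        """
        notes = [rules_label_sections(t) for t in texts]
        if tag_sequences is None:
            tag_sequences = [
                [1 if tag == IN_AP else 0 for tag in n.tags] for n in notes
            ]
        token_lists = [[tok.lower() for tok, _, _ in n.tokens] for n in notes]
        flat = [t for seq in tag_sequences for t in seq]
        if len(set(flat)) < 2:
            raise ValueError("training data contain a single tag class")
        self.vocab_ = self._build_vocab(token_lists)
        V, D, H = len(self.vocab_), self.embed_dim, self.hidden_dim
        rng = np.random.default_rng(self.seed)
        p = {
            "E": (rng.standard_normal((V, D)) * 0.1).astype(np.float64),
            "Wx": (rng.standard_normal((D, H)) * (1.0 / np.sqrt(D))).astype(np.float64),
            "Wh": (rng.standard_normal((H, H)) * (1.0 / np.sqrt(H))).astype(np.float64),
            "bh": np.zeros(H),
            "w": (rng.standard_normal(H) * 0.1).astype(np.float64),
            "c": np.zeros(1),
        }
        m = {k: np.zeros_like(v) for k, v in p.items()}
        v2 = {k: np.zeros_like(v) for k, v in p.items()}
        step = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        order = np.arange(len(notes))
        self.loss_history_ = []
        for epoch in range(self.epochs):
            rng.shuffle(order)
            total = 0.0
            for idx in order:
                ids = self._encode([t for t, _, _ in notes[idx].tokens])
                y = np.asarray(tag_sequences[idx], dtype=np.float64)
                if len(ids) == 0:
                    continue
                loss, grads = self._backprop(p, ids, y)
                total += loss
                gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
                if gnorm > self.clip:
                    for k in grads:
                        grads[k] *= self.clip / gnorm
                step += 1
                for k in p:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v2[k] = beta2 * v2[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1 ** step)
                    vhat = v2[k] / (1 - beta2 ** step)
                    p[k] = p[k] - self.lr * mhat / (np.sqrt(vhat) + eps)
            self.loss_history_.append(total / len(notes))
        self.params_ = p
        return self

    @staticmethod
    def _forward(p, ids):
        T = len(ids)
        H = p["Wh"].shape[0]
        hs = np.zeros((T + 1, H))
        zs = np.zeros((T, H))
        x = p["E"][ids]
        for t in range(T):
            zs[t] = x[t] @ p["Wx"] + hs[t] @ p["Wh"] + p["bh"]
            hs[t + 1] = np.tanh(zs[t])
        logits = hs[1:] @ p["w"] + p["c"]
        return x, hs, logits

    def _backprop(self, p, ids, y):
        x, hs, logits = self._forward(p, ids)
        T = len(ids)
        probs = 1.0 / (1.0 + np.exp(-logits))
        loss = float(
            -np.mean(y * np.log(probs + 1e-12) + (1 - y) * np.log(1 - probs + 1e-12))
        )
        dlogits = (probs - y) / T
        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["w"] = hs[1:].T @ dlogits
        g["c"] = np.array([dlogits.sum()])
        dh_next = np.zeros_like(p["bh"])
        for t in range(T - 1, -1, -1):
            dh = dlogits[t] * p["w"] + dh_next
            dz = dh * (1.0 - hs[t + 1] ** 2)
            g["bh"] += dz
            g["Wx"] += np.outer(x[t], dz)
            g["Wh"] += np.outer(hs[t], dz)
            g["E"][ids[t]] += p["Wx"] @ dz
            dh_next = p["Wh"] @ dz
        return loss, g

    # -- inference ----------------------------------------------------
    def predict_note(self, text: str) -> TokenizedNote:
        tokens = tokenize(text)
        if not tokens:
            return TokenizedNote(text=text, tokens=[], tags=[])
        ids = self._encode([t for t, _, _ in tokens])
        _, _, logits = self._forward(self.params_, ids)
        tags = [IN_AP if l > 0 else OUT_AP for l in logits]
        return TokenizedNote(text=text, tokens=tokens, tags=tags)

    def predict(self, texts):
        """Per-note 0/1 tag arrays (1 = in_ap)."""
        out = []
        for t in texts:
            note = self.predict_note(t)
            out.append(np.array([tag == IN_AP for tag in note.tags], dtype=int))
        return out

    def score(self, texts, tag_sequences=None):
        """Token-level accuracy against given (or rules-derived) tags."""
        if tag_sequences is None:
            tag_sequences = [
                np.array([tag == IN_AP for tag in rules_label_sections(t).tags], dtype=int)
                for t in texts
            ]
        correct = total = 0
        for t, y in zip(texts, tag_sequences):
            pred = self.predict([t])[0]
            y = np.asarray(y)
            correct += int((pred == y).sum())
            total += len(y)
        return correct / total if total else float("nan")


def train_sectioner(texts, tag_sequences=None, **hyperparams) -> RNNSectionTagger:
    """Train the sequence tagger on rules-labeled (or explicitly labeled) notes."""
    return RNNSectionTagger(**hyperparams).fit(texts, tag_sequences)


def extract_assessment_plan(text: str, model: RNNSectionTagger | None = None) -> str:
    """A/P text of a note; the full note when no section is identified."""
    note = (
        rules_label_sections(text) if model is None else model.predict_note(text)
    )
    extracted = note.ap_span_text()
    return extracted if extracted.strip() else text
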