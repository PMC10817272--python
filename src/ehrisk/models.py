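"""Sequence classifiers over encoded visit histories.

Three models share one input convention (per-visit token-index bags, elapsed
days between consecutive visits, static feature tokens merged into the
index-date visit):

* ``TLSTM`` — time-aware LSTM. The previous cell memory is decomposed into a
  learned short-term component ``C_S = tanh(c W_d + b_d)`` and its long-term
  remainder; the short-term part is discounted by ``g(dt) = 1 / log(e + dt)``
  (dt in days) before the standard LSTM gate update. With all gaps zero
  ``g = 1`` and the cell reduces bit-exactly to a standard LSTM.
* ``StandardLSTM`` — the same stack with the time adjustment disabled.
* ``RETAIN`` — reverse-time attention: two recurrent encoders over the visit
  embeddings produce a scalar visit-level attention ``alpha`` (softmax over
  visits) and a coordinate-level gate ``beta``; the context vector
  ``sum_i alpha_i * beta_i * v_i`` feeds a logistic head. ``alpha``/``beta``
  are returned for interpretability.
* ``LogisticBaseline`` — bag-of-token counts plus SDoH covariates through
  scikit-learn logistic regression, exposing the coefficient vector.

Visit embeddings are order-free sums of token embeddings, so permuting
tokens within a visit never changes the output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from ._nn import Tensor, concat, gather_sum
from .encoding import EncodedSample

__all__ = ["ModelConfig", "RiskOutput", "TLSTM", "StandardLSTM", "RETAIN",
           "LogisticBaseline", "default_time_decay", "lr_forward", "make_batch",
           "save_model", "load_model"]


def default_time_decay(delta: np.ndarray) -> np.ndarray:
    """g(dt) = 1 / log(e + dt); g(0) = 1 exactly, decreasing in dt."""
    return 1.0 / np.log(np.e + delta)


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    vocab_size: int                      # including padding index 0
    embed_dim: int = 128
    hidden_size: int = 128
    dropout: float = 0.2
    n_layers: int = 8
    seed: int = 0
    time_decay: Callable[[np.ndarray], np.ndarray] = default_time_decay

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if min(self.vocab_size, self.embed_dim, self.hidden_size, self.n_layers) <= 0:
            raise ValueError("dimensions must be positive")

    def hash(self) -> str:
        key = json.dumps([self.vocab_size, self.embed_dim, self.hidden_size,
                          self.dropout, self.n_layers, self.seed])
        return hashlib.sha256(key.encode()).hexdigest()[:12]


@dataclasses.dataclass
class RiskOutput:
    probability: np.ndarray                 # (B,)
    alpha: np.ndarray | None = None         # (B, T) visit attention
    beta: np.ndarray | None = None          # (B, T, D) coordinate weights


# --------------------------------------------------------------------------
# batching
# --------------------------------------------------------------------------

def make_batch(samples: Sequence[EncodedSample], merge_static: bool = True):
    """Pad a list of encoded samples into dense arrays.

    Static tokens are merged into the newest (index-date) visit; a sample
    with no visits but static tokens gets a single static visit. Returns
    (idx, tok_mask, elapsed, visit_mask).
    """
    seqs, gaps = [], []
    for s in samples:
        visits = [list(v) for v in s.visit_indices]
        elapsed = list(s.elapsed)
        if merge_static and s.static_indices:
            if visits:
                visits[-1] = visits[-1] + list(s.static_indices)
            else:
                visits, elapsed = [list(s.static_indices)], [0]
        if not visits:
            raise ValueError(f"empty sequence for patient {s.patient_id!r}")
        if any(e < 0 for e in elapsed) or elapsed[0] != 0:
            raise ValueError("elapsed times must be nonnegative with first = 0")
        seqs.append(visits)
        gaps.append(elapsed)
    B = len(seqs)
    T = max(len(v) for v in seqs)
    L = max(max(len(visit) for visit in v) for v in seqs)
    idx = np.zeros((B, T, L), dtype=np.int64)
    tok_mask = np.zeros((B, T, L))
    elapsed = np.zeros((B, T))
    visit_mask = np.zeros((B, T))
    for b, (visits, g) in enumerate(zip(seqs, gaps)):
        for t, visit in enumerate(visits):
            idx[b, t, : len(visit)] = visit
            tok_mask[b, t, : len(visit)] = 1.0
        elapsed[b, : len(visits)] = g
        visit_mask[b, : len(visits)] = 1.0
    return idx, tok_mask, elapsed, visit_mask


# --------------------------------------------------------------------------
# recurrent stacks
# --------------------------------------------------------------------------

class _RecurrentBase:
    """Shared parameter plumbing: params as a name -> Tensor dict."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.weights: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(config.seed)
        self.training = False

    def _param(self, name: str, shape: tuple[int, ...], scale: float) -> Tensor:
        t = Tensor(self._rng.uniform(-scale, scale, size=shape), requires_grad=True)
        self.weights[name] = t
        return t

    def params(self) -> list[Tensor]:
        return list(self.weights.values())

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.weights.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.weights.items():
            v.data = state[k].copy()

    def train(self, mode: bool = True) -> None:
        self.training = mode

    def eval(self) -> None:
        self.training = False

    def _dropout(self, x: Tensor) -> Tensor:
        p = self.config.dropout
        if not self.training or p == 0.0:
            return x
        keep = (self._rng.random(x.shape) >= p) / (1.0 - p)
        return x * keep


    def _lstm_stack(self, prefix: str, n_layers: int, x_seq: list[Tensor],
                    elapsed: np.ndarray, visit_mask: np.ndarray,
                    time_aware: bool) -> list[Tensor]:
        """Run a (time-aware) LSTM stack; returns hidden states per step of
        the top layer. x_seq: list over T of (B, D_in) tensors; `elapsed`
        aligned with x_seq order."""
        H = self.config.hidden_size
        B = x_seq[0].shape[0]
        g = self.config.time_decay(elapsed)          # (B, T)
        seq = x_seq
        for layer in range(n_layers):
            W = self.weights[f"{prefix}W{layer}"]
            U = self.weights[f"{prefix}U{layer}"]
            b = self.weights[f"{prefix}b{layer}"]
            h = Tensor(np.zeros((B, H)))
            c = Tensor(np.zeros((B, H)))
            outs: list[Tensor] = []
            for t, x in enumerate(seq):
                if time_aware:
                    Wd = self.weights[f"{prefix}Wd{layer}"]
                    bd = self.weights[f"{prefix}bd{layer}"]
                    cs = (c @ Wd + bd).tanh()
                    # c - cs*(1-g): bitwise identical to c when g == 1
                    c_star = c - cs * (1.0 - g[:, t : t + 1])
                else:
                    c_star = c
                gates = x @ W + h @ U + b
                i = gates[:, :H].sigmoid()
                f = gates[:, H : 2 * H].sigmoid()
                cand = gates[:, 2 * H : 3 * H].tanh()
                o = gates[:, 3 * H :].sigmoid()
                c_new = f * c_star + i * cand
                h_new = o * c_new.tanh()
                m = visit_mask[:, t : t + 1]
                c = c_new * m + c * (1.0 - m)
                h = h_new * m + h * (1.0 - m)
                outs.append(h)
            seq = [self._dropout(s) for s in outs] if layer < n_layers - 1 else outs
        return seq

    def _init_lstm_stack(self, prefix: str, n_layers: int, input_dim: int,
                         time_aware: bool) -> None:
        H = self.config.hidden_size
        scale = 1.0 / np.sqrt(H)
        for layer in range(n_layers):
            d_in = input_dim if layer == 0 else H
            self._param(f"{prefix}W{layer}", (d_in, 4 * H), scale)
            self._param(f"{prefix}U{layer}", (H, 4 * H), scale)
            b = self._param(f"{prefix}b{layer}", (4 * H,), scale)
            b.data[H : 2 * H] += 1.0        # forget-gate bias: retain memory
            if time_aware:
                self._param(f"{prefix}Wd{layer}", (H, H), scale)
                self._param(f"{prefix}bd{layer}", (H,), scale)

    def _embed(self, idx: np.ndarray, tok_mask: np.ndarray) -> Tensor:
        return gather_sum(self.weights["E"], idx, tok_mask)

    # prediction helpers ---------------------------------------------------
    def forward_batch(self, batch, training: bool = False) -> Tensor:
        raise NotImplementedError

    def predict_proba(self, samples: Sequence[EncodedSample],
                      chunk: int = 256) -> np.ndarray:
        was_training = self.training
        self.eval()
        out = []
        for k in range(0, len(samples), chunk):
            batch = make_batch(samples[k : k + chunk])
            out.append(self.forward_batch(batch).data)
        self.train(was_training)
        return np.concatenate(out) if out else np.empty(0)


class TLSTM(_RecurrentBase):
    """Stacked time-aware LSTM with a sigmoid risk head."""

    time_aware = True

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        D, H = config.embed_dim, config.hidden_size
        scale = 1.0 / np.sqrt(H)
        self._param("E", (config.vocab_size, D), 1.0 / np.sqrt(D))
        self.weights["E"].data[0] = 0.0          # padding row
        self._init_lstm_stack("", config.n_layers, D, self.time_aware)
        self._param("w_out", (H, 1), scale)
        self._param("b_out", (1,), scale)

    def forward_batch(self, batch, training: bool | None = None) -> Tensor:
        if training is not None:
            self.train(training)
        idx, tok_mask, elapsed, visit_mask = batch
        if np.any(elapsed < 0):
            raise ValueError("negative elapsed time")
        v = self._embed(idx, tok_mask)            # (B, T, D)
        # dropout applies between recurrent layers and pre-head, not on the
        # token-level inputs (sparse presence signals)
        x_seq = [v[:, t, :] for t in range(v.shape[1])]
        hs = self._lstm_stack("", self.config.n_layers, x_seq, elapsed,
                              visit_mask, self.time_aware)
        h_last = self._dropout(hs[-1])            # masked carry => last real state
        logit = h_last @ self.weights["w_out"] + self.weights["b_out"]
        return logit[:, 0].sigmoid()

    def forward(self, sample: EncodedSample) -> RiskOutput:
        p = self.forward_batch(make_batch([sample]), training=False)
        return RiskOutput(probability=p.data)


class StandardLSTM(TLSTM):
    """TLSTM stack with the elapsed-time adjustment disabled."""

    time_aware = False


class RETAIN(_RecurrentBase):
    """Reverse-time attention model.

    The configured layer budget is split evenly between the alpha (visit-
    level) and beta (coordinate-level) encoders; both run over the sequence
    in reverse time, mirroring how a clinician weighs recent visits first.
    """

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        D, H = config.embed_dim, config.hidden_size
        scale = 1.0 / np.sqrt(H)
        self.n_alpha = max(1, config.n_layers // 2)
        self.n_beta = max(1, config.n_layers - self.n_alpha)
        self._param("E", (config.vocab_size, D), 1.0 / np.sqrt(D))
        self.weights["E"].data[0] = 0.0
        self._init_lstm_stack("a_", self.n_alpha, D, time_aware=False)
        self._init_lstm_stack("b_", self.n_beta, D, time_aware=False)
        self._param("w_alpha", (H, 1), scale)
        self._param("b_alpha", (1,), scale)
        self._param("W_beta", (H, D), scale)
        self._param("b_beta", (D,), scale)
        self._param("w_out", (D, 1), scale)
        self._param("b_out", (1,), scale)

    def forward_batch(self, batch, training: bool | None = None,
                      return_attention: bool = False):
        if training is not None:
            self.train(training)
        idx, tok_mask, elapsed, visit_mask = batch
        B, T, _ = idx.shape
        v = self._embed(idx, tok_mask)            # (B, T, D)
        v_steps = [v[:, t, :] for t in range(T)]
        # reverse time; padded steps sit at the front and are masked out
        rev = list(reversed(range(T)))
        rev_mask = visit_mask[:, rev]
        zeros = np.zeros((B, T))
        x_rev = [v_steps[t] for t in rev]
        ha = self._lstm_stack("a_", self.n_alpha, x_rev, zeros, rev_mask, False)
        hb = self._lstm_stack("b_", self.n_beta, x_rev, zeros, rev_mask, False)
        # back to forward order
        ha = [ha[T - 1 - t] for t in range(T)]
        hb = [hb[T - 1 - t] for t in range(T)]

        e = concat([ha[t] @ self.weights["w_alpha"] + self.weights["b_alpha"]
                    for t in range(T)], axis=1)   # (B, T)
        neg = (1.0 - visit_mask) * 1e9
        e_shift = e - e.data.max(axis=1, keepdims=True) - neg
        ex = e_shift.exp() * visit_mask
        alpha = ex / ex.sum(axis=1, keepdims=True)

        ctx = None
        betas = []
        for t in range(T):
            beta_t = (hb[t] @ self.weights["W_beta"] + self.weights["b_beta"]).tanh()
            betas.append(beta_t)
            term = alpha[:, t : t + 1] * beta_t * v_steps[t]
            ctx = term if ctx is None else ctx + term
        ctx = self._dropout(ctx)
        logit = ctx @ self.weights["w_out"] + self.weights["b_out"]
        p = logit[:, 0].sigmoid()
        if return_attention:
            beta_arr = np.stack([b.data for b in betas], axis=1)
            return p, alpha.data, beta_arr
        return p

    def forward(self, sample: EncodedSample) -> RiskOutput:
        p, alpha, beta = self.forward_batch(make_batch([sample]), training=False,
                                            return_attention=True)
        return RiskOutput(probability=p.data, alpha=alpha, beta=beta)


# --------------------------------------------------------------------------
# logistic baseline
# --------------------------------------------------------------------------

def lr_forward(features: np.ndarray, coef: np.ndarray, intercept: float) -> np.ndarray:
    """Plain logistic score sigma(x . coef + intercept)."""
    z = np.asarray(features) @ np.asarray(coef) + intercept
    return 1.0 / (1.0 + np.exp(-z))


class LogisticBaseline:
    """Bag-of-token counts + SDoH covariates through logistic regression."""

    def __init__(self, vocab_size: int, n_covariates: int = 0, C: float = 1.0,
                 covariate_names: Sequence[str] | None = None, seed: int = 0):
        self.vocab_size = vocab_size
        self.n_covariates = n_covariates
        self.covariate_names = list(covariate_names or
                                    [f"cov{i}" for i in range(n_covariates)])
        self._clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)

    def _design(self, samples: Sequence[EncodedSample]) -> np.ndarray:
        X = np.zeros((len(samples), self.vocab_size + self.n_covariates))
        for r, s in enumerate(samples):
            for visit in s.visit_indices:
                for i in visit:
                    X[r, i] += 1.0
            for i in s.static_indices:
                X[r, i] += 1.0
            if self.n_covariates and s.covariates is not None:
                X[r, self.vocab_size :] = s.covariates
        return X

    def fit(self, samples: Sequence[EncodedSample]) -> "LogisticBaseline":
        y = np.array([s.y for s in samples])
        self._clf.fit(self._design(samples), y)
        return self

    def predict_proba(self, samples: Sequence[EncodedSample]) -> np.ndarray:
        return self._clf.predict_proba(self._design(samples))[:, 1]

    @property
    def coef_(self) -> np.ndarray:
        return self._clf.coef_[0]

    @property
    def intercept_(self) -> float:
        return float(self._clf.intercept_[0])

    def covariate_coefficients(self) -> dict[str, float]:
        tail = self.coef_[self.vocab_size :]
        return dict(zip(self.covariate_names, tail))


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_model(model: _RecurrentBase, path: str) -> None:
    """Single-file checkpoint with a config hash guarding reload."""
    np.savez(path, __config_hash=np.array(model.config.hash()),
             __class=np.array(type(model).__name__), **model.get_state())


def load_model(path: str, config: ModelConfig) -> _RecurrentBase:
    data = np.load(path, allow_pickle=False)
    if str(data["__config_hash"]) != config.hash():
        raise ValueError("checkpoint config hash mismatch")
    cls = {"TLSTM": TLSTM, "StandardLSTM": StandardLSTM, "RETAIN": RETAIN}[
        str(data["__class"])]
    model = cls(config)
    model.set_state({k: data[k] for k in model.weights})
    return model
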