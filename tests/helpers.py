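"""Hand-computed scalar oracles shared by the model tests.

These re-implement the recurrent cells with plain Python floats, written
independently of the array implementation so they can serve as oracles.
"""

import math


def sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def tlstm_scalar_forward(weights: dict, visit_inputs: list[float],
                         gaps: list[float], time_aware: bool = True) -> float:
    """One-dimensional time-aware LSTM forward pass.

    `weights` holds scalars: wi, wf, wc, wo (input weights), ui, uf, uc, uo
    (recurrent), bi, bf, bc, bo (biases), wd, bd (memory decomposition),
    w_out, b_out (head). Returns the sigmoid risk probability.
    """
    h = c = 0.0
    for x, gap in zip(visit_inputs, gaps):
        if time_aware:
            cs = math.tanh(c * weights["wd"] + weights["bd"])
            g = 1.0 / math.log(math.e + gap)
            c_star = c - cs * (1.0 - g)
        else:
            c_star = c
        i = sigmoid(x * weights["wi"] + h * weights["ui"] + weights["bi"])
        f = sigmoid(x * weights["wf"] + h * weights["uf"] + weights["bf"])
        cand = math.tanh(x * weights["wc"] + h * weights["uc"] + weights["bc"])
        o = sigmoid(x * weights["wo"] + h * weights["uo"] + weights["bo"])
        c = f * c_star + i * cand
        h = o * math.tanh(c)
    return sigmoid(h * weights["w_out"] + weights["b_out"])


def lstm_scalar_hidden(weights: dict, inputs: list[float]) -> list[float]:
    """Hidden-state sequence of a 1-dim plain LSTM (same weight naming)."""
    h = c = 0.0
    out = []
    for x in inputs:
        i = sigmoid(x * weights["wi"] + h * weights["ui"] + weights["bi"])
        f = sigmoid(x * weights["wf"] + h * weights["uf"] + weights["bf"])
        cand = math.tanh(x * weights["wc"] + h * weights["uc"] + weights["bc"])
        o = sigmoid(x * weights["wo"] + h * weights["uo"] + weights["bo"])
        c = f * c + i * cand
        h = o * math.tanh(c)
        out.append(h)
    return out


def retain_scalar_forward(weights: dict, visit_inputs: list[float]) -> float:
    """One-dimensional reverse-time attention forward pass.

    Alpha and beta encoders are 1-dim plain LSTMs (weights prefixed a_/b_),
    run over the reversed visit sequence; w_alpha/b_alpha give the scalar
    attention logits (softmax over visits), W_beta/b_beta the tanh gate, and
    w_out/b_out the logistic head on sum_i alpha_i * beta_i * v_i.
    """
    rev = list(reversed(visit_inputs))
    ha = lstm_scalar_hidden({k[2:]: v for k, v in weights.items()
                             if k.startswith("a_")}, rev)
    hb = lstm_scalar_hidden({k[2:]: v for k, v in weights.items()
                             if k.startswith("b_")}, rev)
    ha, hb = ha[::-1], hb[::-1]
    logits = [h * weights["w_alpha"] + weights["b_alpha"] for h in ha]
    mx = max(logits)
    ex = [math.exp(e - mx) for e in logits]
    alphas = [e / sum(ex) for e in ex]
    betas = [math.tanh(h * weights["W_beta"] + weights["b_beta"]) for h in hb]
    ctx = sum(a * b * v for a, b, v in zip(alphas, betas, visit_inputs))
    return sigmoid(ctx * weights["w_out"] + weights["b_out"])
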