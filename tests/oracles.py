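"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as straight-line scalar code
(loops, explicit formulas), sharing no implementation with the package,
so that agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# scalar graph-transformer forward pass

def _affine(W, b, x):
    return [sum(W[r][c] * x[r] for r in range(len(x))) + b[c] for c in range(len(b))]


def _layer_norm_scalar(x, gamma, beta, eps=1e-5):
    n = len(x)
    mu = sum(x) / n
    var = sum((xi - mu) ** 2 for xi in x) / n
    return [(xi - mu) / math.sqrt(var + eps) * g + b for xi, g, b in zip(x, gamma, beta)]


def scalar_forward(X, E, A, params, config, collect_alphas=None):
    """Loop-based forward pass of the edge-aware graph transformer.

    X: (n, D) node features, E: (n, n, F) edge features (already
    transformed the same way the model transforms its inputs), A: (n, n)
    0/1 adjacency. ``params`` is a promethyl ModelParams; only its raw
    numpy arrays are read. Returns an (n, out_dim) array of predictions.
    """
    n = len(X)
    H, d = config.n_heads, config.head_dim
    x = [list(map(float, row)) for row in X]
    e_state = [[list(map(float, E[i][j])) for j in range(n)] for i in range(n)]
    n_blocks = len(params.blocks)
    for o, block in enumerate(params.blocks):
        last = o == n_blocks - 1
        per_head_msgs = []
        per_head_alphas = []
        for h in range(H):
            Wq = block[f"h{h}_Wq"].data; bq = block[f"h{h}_bq"].data
            Wk = block[f"h{h}_Wk"].data; bk = block[f"h{h}_bk"].data
            Wv = block[f"h{h}_Wv"].data; bv = block[f"h{h}_bv"].data
            We = block[f"h{h}_We"].data; be = block[f"h{h}_be"].data
            q = [_affine(Wq, bq, x[i]) for i in range(n)]
            k = [_affine(Wk, bk, x[j]) for j in range(n)]
            v = [_affine(Wv, bv, x[j]) for j in range(n)]
            e = [[_affine(We, be, e_state[i][j]) for j in range(n)] for i in range(n)]
            alpha = [[0.0] * n for _ in range(n)]
            msgs = []
            for i in range(n):
                neighbors = [j for j in range(n) if A[i][j]]
                terms = {}
                for j in neighbors:
                    dot = sum(q[i][c] * (k[j][c] + e[i][j][c]) for c in range(d))
                    terms[j] = math.exp(dot / math.sqrt(d))
                z = sum(terms.values())
                msg = [0.0] * d
                for j in neighbors:
                    alpha[i][j] = terms[j] / z
                    for c in range(d):
                        msg[c] += alpha[i][j] * (v[j][c] + e[i][j][c])
                msgs.append(msg)
            per_head_msgs.append(msgs)
            per_head_alphas.append(alpha)
        if collect_alphas is not None:
            collect_alphas.append(per_head_alphas)
        new_x = []
        for i in range(n):
            if last:
                p_hat = [
                    sum(per_head_msgs[h][i][c] for h in range(H)) / H for c in range(d)
                ]
            else:
                p_hat = [per_head_msgs[h][i][c] for h in range(H) for c in range(d)]
            normed = _layer_norm_scalar(
                p_hat, block["ln_node_g"].data, block["ln_node_b"].data
            )
            new_x.append([max(0.0, z) for z in normed])
        if not last:
            new_e = [[None] * n for _ in range(n)]
            for i in range(n):
                for j in range(n):
                    cat = []
                    for h in range(H):
                        cat.append(per_head_alphas[h][i][j])
                        cat.extend(e_state[i][j])
                    normed = _layer_norm_scalar(
                        cat, block["ln_edge_g"].data, block["ln_edge_b"].data
                    )
                    new_e[i][j] = [max(0.0, z) for z in normed]
            e_state = new_e
        x = new_x
    W, b = params.w_out.data, params.b_out.data
    out = []
    for i in range(n):
        row = _affine(W, b, x[i])
        out.append([1.0 / (1.0 + math.exp(-z)) for z in row])
    return np.array(out)


# ---------------------------------------------------------------------------
# metric oracles

def mcc_confusion(true_labels, pred_labels) -> float:
    tp = sum(1 for t, p in zip(true_labels, pred_labels) if t == 1 and p == 1)
    tn = sum(1 for t, p in zip(true_labels, pred_labels) if t == 0 and p == 0)
    fp = sum(1 for t, p in zip(true_labels, pred_labels) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(true_labels, pred_labels) if t == 1 and p == 0)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def auc_mann_whitney(labels, scores) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def ap_recall_increment(labels, scores) -> float:
    """Average precision as the precision-weighted sum of recall increments.

    Tied scores share a threshold, so they enter the precision-recall
    curve together.
    """
    n_pos = sum(labels)
    tp = 0
    seen = 0
    ap = 0.0
    prev_recall = 0.0
    for threshold in sorted(set(scores), reverse=True):
        batch = [i for i, s in enumerate(scores) if s == threshold]
        tp += sum(labels[i] for i in batch)
        seen += len(batch)
        recall = tp / n_pos
        precision = tp / seen
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


def ari_contingency(a, b) -> float:
    """Adjusted Rand index straight from the pair-counting formula."""
    la, lb = sorted(set(a)), sorted(set(b))
    table = [[sum(1 for x, y in zip(a, b) if x == i and y == j) for j in lb] for i in la]
    comb2 = lambda m: m * (m - 1) / 2
    sum_ij = sum(comb2(nij) for row in table for nij in row)
    sum_a = sum(comb2(sum(row)) for row in table)
    sum_b = sum(comb2(sum(table[i][j] for i in range(len(la)))) for j in range(len(lb)))
    n = len(a)
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 0.0
    return (sum_ij - expected) / (max_index - expected)
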