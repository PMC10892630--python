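"""Minimal gated recurrent sequence model in NumPy.

A single-layer GRU with a per-position softmax head, trained autoregressively
with teacher forcing under categorical cross-entropy.  Written for small
token-sequence corpora (a few thousand sequences, vocabularies of a few tens
of symbols) where exact seed-for-seed reproducibility matters more than raw
throughput.

Shapes: B batch, T time, V vocabulary, H hidden.
"""

from __future__ import annotations

import numpy as np

__all__ = ["init_params", "loss_and_grads", "sample_tokens", "adam_step", "init_adam"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def init_params(vocab_size: int, hidden: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-scaled parameter initialization."""
    V, H = vocab_size, hidden

    def mat(n_in, n_out):
        return rng.normal(0.0, np.sqrt(2.0 / (n_in + n_out)), size=(n_in, n_out))

    params = {}
    for gate in ("z", "r", "h"):
        params[f"W{gate}"] = mat(V, H)
        params[f"U{gate}"] = mat(H, H)
        params[f"b{gate}"] = np.zeros(H)
    params["Wy"] = mat(H, V)
    params["by"] = np.zeros(V)
    return params


def _step(params, x, h_prev):
    """One GRU step. x: (B,V) one-hot, h_prev: (B,H)."""
    z = _sigmoid(x @ params["Wz"] + h_prev @ params["Uz"] + params["bz"])
    r = _sigmoid(x @ params["Wr"] + h_prev @ params["Ur"] + params["br"])
    rh = r * h_prev
    c = np.tanh(x @ params["Wh"] + rh @ params["Uh"] + params["bh"])
    h = (1.0 - z) * h_prev + z * c
    return h, (z, r, rh, c, h_prev)


def loss_and_grads(
    params: dict[str, np.ndarray],
    inputs: np.ndarray,
    targets: np.ndarray,
    pad_index: int = 0,
    compute_grads: bool = True,
) -> tuple[float, dict[str, np.ndarray] | None]:
    """Masked mean cross-entropy of next-token prediction, with BPTT gradients.

    ``inputs``/``targets`` are (B, T) integer token matrices; positions whose
    target equals ``pad_index`` are excluded from the loss.
    """
    B, T = inputs.shape
    V = params["by"].shape[0]
    H = params["bz"].shape[0]
    eye = np.eye(V)

    h = np.zeros((B, H))
    caches = []
    mask = targets != pad_index
    n_tokens = int(mask.sum())
    if n_tokens == 0:
        raise ValueError("no non-padding targets in batch")

    loss = 0.0
    probs_t = []
    for t in range(T):
        x = eye[inputs[:, t]]
        h, cache = _step(params, x, h)
        logits = h @ params["Wy"] + params["by"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        p = e / e.sum(axis=1, keepdims=True)
        m = mask[:, t]
        if m.any():
            loss -= np.log(p[m, targets[m, t]] + 1e-12).sum()
        caches.append((x, h, cache))
        probs_t.append(p)
    loss /= n_tokens

    if not compute_grads:
        return float(loss), None

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dh_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x, h_t, (z, r, rh, c, h_prev) = caches[t]
        p = probs_t[t].copy()
        m = mask[:, t]
        dlogits = np.zeros_like(p)
        if m.any():
            p_m = p[m]
            p_m[np.arange(p_m.shape[0]), targets[m, t]] -= 1.0
            dlogits[m] = p_m / n_tokens
        grads["Wy"] += h_t.T @ dlogits
        grads["by"] += dlogits.sum(axis=0)
        dh = dh_next + dlogits @ params["Wy"].T

        dz = dh * (c - h_prev)
        dc = dh * z
        dh_prev = dh * (1.0 - z)

        dc_pre = dc * (1.0 - c * c)
        grads["Wh"] += x.T @ dc_pre
        grads["Uh"] += rh.T @ dc_pre
        grads["bh"] += dc_pre.sum(axis=0)
        drh = dc_pre @ params["Uh"].T
        dr = drh * h_prev
        dh_prev += drh * r

        dz_pre = dz * z * (1.0 - z)
        dr_pre = dr * r * (1.0 - r)
        for gate, dpre in (("z", dz_pre), ("r", dr_pre)):
            grads[f"W{gate}"] += x.T @ dpre
            grads[f"U{gate}"] += h_prev.T @ dpre
            grads[f"b{gate}"] += dpre.sum(axis=0)
            dh_prev += dpre @ params[f"U{gate}"].T
        dh_next = dh_prev

    return float(loss), grads


def init_adam(params: dict[str, np.ndarray]) -> dict:
    return {
        "m": {k: np.zeros_like(v) for k, v in params.items()},
        "v": {k: np.zeros_like(v) for k, v in params.items()},
        "t": 0,
    }


def adam_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: dict,
    lr: float = 5e-3,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
    clip: float = 5.0,
) -> None:
    """In-place adaptive-moment update with global gradient-norm clipping."""
    norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    scale = clip / norm if norm > clip else 1.0
    state["t"] += 1
    t = state["t"]
    for k in params:
        g = grads[k] * scale
        state["m"][k] = beta1 * state["m"][k] + (1 - beta1) * g
        state["v"][k] = beta2 * state["v"][k] + (1 - beta2) * g * g
        m_hat = state["m"][k] / (1 - beta1**t)
        v_hat = state["v"][k] / (1 - beta2**t)
        params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)


def sample_tokens(
    params: dict[str, np.ndarray],
    n: int,
    max_len: int,
    bos_index: int,
    eos_index: int,
    pad_index: int,
    temperature: float,
    rng: np.random.Generator,
) -> list[list[int]]:
    """Draw ``n`` token sequences by autoregressive multinomial sampling.

    All sequences are advanced in parallel; each stops at its end-of-sequence
    symbol or at ``max_len`` tokens.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    V = params["by"].shape[0]
    H = params["bz"].shape[0]
    eye = np.eye(V)
    h = np.zeros((n, H))
    current = np.full(n, bos_index, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    out: list[list[int]] = [[] for _ in range(n)]
    for _ in range(max_len):
        x = eye[current]
        h, _ = _step(params, x, h)
        logits = (h @ params["Wy"] + params["by"]) / temperature
        logits[:, pad_index] = -np.inf
        logits[:, bos_index] = -np.inf
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        # inverse-CDF draw per row keeps a single deterministic RNG stream
        u = rng.random(n)
        nxt = (p.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(max=V - 1)
        for i in range(n):
            if not alive[i]:
                continue
            if nxt[i] == eos_index:
                alive[i] = False
            else:
                out[i].append(int(nxt[i]))
        current = np.where(alive, nxt, pad_index)
        if not alive.any():
            break
    return out
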