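"""Assembly of classifier weights into a non-negative 3-way weight tensor.

Each linear classifier's weight vector is L1-normalized, then split by sign:
positive weights speak for the awake state, negative weights (in absolute
value) for the unconscious state, because the causality features themselves
are non-negative. The resulting non-negative "weight data" are aligned into
a tensor with dimensions (condition-sample pairs) x (frequency) x
(state-tagged electrode-pair features), concatenating electrode pairs over
datasets, region pairs, both causal directions and the two states — ready
for the trilinear decomposition stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import FeatureSet

__all__ = [
    "Axis3Entry",
    "WeightTensor",
    "normalize_weights",
    "split_signs",
    "assemble_tensor",
]


@dataclass(frozen=True)
class Axis3Entry:
    """Book-keeping for one slot of the electrode-pair axis."""

    dataset: str
    src: str
    dst: str
    state: str  # "awake" or "unconscious"


@dataclass
class WeightTensor:
    """Weight data: (n_sample_pairs, n_freq, n_axis3), all entries >= 0."""

    data: np.ndarray
    axis3: list[Axis3Entry]
    freqs: np.ndarray
    n_sample_pairs: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("weight tensor must be 3-way")
        if self.data.shape != (self.n_sample_pairs, len(self.freqs), len(self.axis3)):
            raise ValueError("axis bookkeeping does not match data shape")
        if np.any(self.data < 0):
            raise ValueError("weight tensor must be non-negative")

    def axis3_index(self) -> dict[Axis3Entry, int]:
        return {e: k for k, e in enumerate(self.axis3)}


def normalize_weights(w: np.ndarray) -> np.ndarray:
    """Divide a weight vector by the sum of absolute values; signs preserved."""
    w = np.asarray(w, dtype=float)
    norm = np.sum(np.abs(w))
    if norm == 0:
        raise ValueError("cannot normalize an all-zero weight vector")
    return w / norm


def split_signs(w_norm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a signed weight vector into (awake part, unconscious part).

    awake = max(w, 0); unconscious = max(-w, 0). Both parts are
    non-negative, have disjoint supports, and awake - unconscious
    reconstructs the input exactly.
    """
    w_norm = np.asarray(w_norm, dtype=float)
    return np.maximum(w_norm, 0.0), np.maximum(-w_norm, 0.0)


def assemble_tensor(
    datasets: dict[str, dict[tuple[str, str], tuple[np.ndarray, FeatureSet]]],
    freqs: np.ndarray,
    states: tuple[str, str] = ("awake", "unconscious"),
) -> WeightTensor:
    """Align normalized, sign-split weights from all datasets into one tensor.

    ``datasets`` maps dataset name -> {region pair -> (W, feature set)}
    where W is (n_sample_pairs, d) raw classifier weights with d =
    n_dirpairs x n_freq, laid out dirpair-major as fixed by
    ``classify.build_features``. Missing region pairs simply contribute
    nothing. Per classifier slice, awake part + unconscious part sum to 1
    exactly (L1 normalization before sign-splitting).
    """
    freqs = np.asarray(freqs, dtype=float)
    n_freq = freqs.size
    n_sp = None
    axis3: list[Axis3Entry] = []
    blocks: list[np.ndarray] = []  # each (n_sp, n_freq, n_dirpairs*2)
    for ds_name in datasets:
        for (ra, rb), (W, fs) in datasets[ds_name].items():
            W = np.asarray(W, dtype=float)
            d = W.shape[1]
            if d % n_freq != 0:
                raise ValueError(
                    f"weight length {d} is not a multiple of the frequency grid ({n_freq})"
                )
            n_dp = d // n_freq
            dirpairs = [fs.columns[k * n_freq][:2] for k in range(n_dp)]
            for k in range(n_dp):
                got = {c[:2] for c in fs.columns[k * n_freq : (k + 1) * n_freq]}
                if got != {dirpairs[k]}:
                    raise ValueError("feature columns are not dirpair-major")
            if n_sp is None:
                n_sp = W.shape[0]
            elif W.shape[0] != n_sp:
                raise ValueError("condition-sample-pair count mismatch across classifiers")
            pos_block = np.empty((n_sp, n_freq, n_dp))
            neg_block = np.empty((n_sp, n_freq, n_dp))
            for sp in range(n_sp):
                wn = normalize_weights(W[sp])
                pos, neg = split_signs(wn)
                pos_block[sp] = pos.reshape(n_dp, n_freq).T
                neg_block[sp] = neg.reshape(n_dp, n_freq).T
            blocks.append(pos_block)
            axis3.extend(Axis3Entry(ds_name, s, t, states[0]) for s, t in dirpairs)
            blocks.append(neg_block)
            axis3.extend(Axis3Entry(ds_name, s, t, states[1]) for s, t in dirpairs)
    if n_sp is None:
        raise ValueError("no classifier weights given")
    data = np.concatenate(blocks, axis=2)
    return WeightTensor(data=data, axis3=axis3, freqs=freqs, n_sample_pairs=n_sp)
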