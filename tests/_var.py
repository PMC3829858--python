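"""Shared helpers: direct simulation of bivariate VAR models for oracles."""

import numpy as np

from gcflow.specgc import VarModel, spectral_granger


def simulate_var(model: VarModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate (2, n) from a bivariate VAR with Gaussian innovations."""
    p = model.order
    burn = 2000
    L = np.linalg.cholesky(model.sigma)
    eps = L @ rng.standard_normal((2, n + burn))
    x = np.zeros((2, n + burn))
    for t in range(p, n + burn):
        x[:, t] = eps[:, t] + sum(model.coefs[k] @ x[:, t - k - 1] for k in range(p))
    return x[:, burn:]


def as_trials(x: np.ndarray, trial_len: int) -> np.ndarray:
    """Slice a long (2, n) series into (n_trials, 2, trial_len) pseudo-trials."""
    n_trials = x.shape[1] // trial_len
    return x[:, : n_trials * trial_len].reshape(2, n_trials, trial_len).transpose(1, 0, 2)


def random_stable_var(rng: np.random.Generator, p: int = 3,
                      max_radius: float = 0.9) -> VarModel:
    """Random stable bivariate VAR(p) with decaying lag coefficients."""
    while True:
        A = rng.normal(0, 0.25, size=(p, 2, 2)) * (0.7 ** np.arange(p))[:, None, None]
        L = rng.normal(0, 0.5, size=(2, 2))
        S = L @ L.T + 0.3 * np.eye(2)
        m = VarModel(order=p, coefs=A, sigma=S, rate=200.0)
        if m.companion_radius() < max_radius:
            return m


def random_identity_regime_var(rng: np.random.Generator, p: int = 3) -> VarModel:
    """Random stable VAR(3) with substantial bidirectional causality, drawn
    from the regime where the spectral decomposition integrates exactly to
    the time-domain measure (minimum-phase intrinsic spectral factors)."""
    nf = 2048
    freqs = (np.arange(nf) + 0.5) / nf * 100.0
    k = np.arange(1, p + 1)
    while True:
        A = rng.normal(0, 0.3, size=(p, 2, 2)) * (0.7 ** np.arange(p))[:, None, None]
        A[:, 0, 1] += rng.uniform(0.2, 0.5) * np.sign(rng.normal()) * (0.7 ** np.arange(p))
        A[:, 1, 0] += rng.uniform(0.2, 0.5) * np.sign(rng.normal()) * (0.7 ** np.arange(p))
        L = rng.normal(0, 0.5, size=(2, 2))
        S = L @ L.T + 0.3 * np.eye(2)
        m = VarModel(order=p, coefs=A, sigma=S, rate=200.0)
        if m.companion_radius() >= 0.9:
            continue
        spec = spectral_granger(m, freqs)
        if spec.values.mean(axis=1).min() <= 0.25:
            continue
        phase = np.exp(-2j * np.pi * freqs[:, None] * k[None, :] / m.rate)
        Af = np.eye(2)[None] - np.einsum("fk,kij->fij", phase, m.coefs)
        H = np.linalg.inv(Af)
        Sf = H @ m.sigma @ np.conj(H.transpose(0, 2, 1))
        v2_1 = S[1, 1] - S[0, 1] ** 2 / S[0, 0]
        v1_2 = S[0, 0] - S[0, 1] ** 2 / S[1, 1]
        i11 = np.real(Sf[:, 0, 0]) - v2_1 * np.abs(H[:, 0, 1]) ** 2
        i22 = np.real(Sf[:, 1, 1]) - v1_2 * np.abs(H[:, 1, 0]) ** 2
        if i11.min() <= 0 or i22.min() <= 0:
            continue
        r1 = np.exp(np.mean(np.log(i11))) / S[0, 0]
        r2 = np.exp(np.mean(np.log(i22))) / S[1, 1]
        if abs(r1 - 1) < 1e-6 and abs(r2 - 1) < 1e-6:
            return m
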