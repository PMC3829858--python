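"""Non-negative PARAFAC of the weight tensor and all derived summaries.

The trilinear model X ~ sum_r a_r (x) b_r (x) c_r with non-negativity
constraints on all three modes is fitted by hierarchical alternating least
squares (HALS), restarted from several random initializations. The number
of components is chosen with the core consistency diagnostic (CCD): the
largest k for which the least-squares Tucker core implied by the PARAFAC
loadings stays close to a superdiagonal array (CCD > 40%).

Derived summaries operationalize the figures of this kind of analysis:
per-component frequency peaks, directed region-score matrices and their
directional (top-down minus bottom-up) differences, per-electrode
outflow/inflow maps, spatial-frequency correlations between component sets,
and an individual-consistency ratio across datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .tensorize import Axis3Entry, WeightTensor

__all__ = [
    "ComponentSet",
    "parafac_fit",
    "core_consistency",
    "select_components",
    "frequency_peak",
    "region_scores",
    "directional_difference",
    "electrode_flow",
    "spatial_frequency_correlation",
    "individual_consistency",
    "tucker_congruence",
    "match_components",
    "state_dominance",
]

log = logging.getLogger(__name__)


@dataclass
class ComponentSet:
    """Fitted non-negative PARAFAC model.

    ``factors`` = [A, B, C] with columns as components, ordered by
    descending explained variation; for the weight tensor A holds
    condition-sample-pair scores, B frequency scores, C electrode-pair
    scores. ``fit_pct`` is 100 (1 - ||X - Xhat||^2 / ||X||^2).
    """

    factors: list[np.ndarray]
    fit_pct: float
    k: int
    ccd_pct: float | None = None

    @property
    def sample_scores(self) -> np.ndarray:
        return self.factors[0]

    @property
    def freq_scores(self) -> np.ndarray:
        return self.factors[1]

    @property
    def space_scores(self) -> np.ndarray:
        return self.factors[2]

    def reconstruct(self) -> np.ndarray:
        A, B, C = self.factors
        return np.einsum("ir,jr,kr->ijk", A, B, C)


def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    k = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, k)


def _hals_once(
    x: np.ndarray, k: int, rng: np.random.Generator,
    tol: float, max_iter: int,
) -> tuple[list[np.ndarray], float, bool]:
    """One HALS run from a random non-negative initialization."""
    dims = x.shape
    factors = [rng.uniform(0.1, 1.0, size=(d, k)) for d in dims]
    unfolds = [_unfold(x, m) for m in range(3)]
    norm_x2 = float(np.sum(x * x))
    if norm_x2 == 0:
        raise ValueError("cannot decompose an all-zero tensor")
    # scale the initialization so the initial model has the data's magnitude;
    # badly scaled starts make HALS clip whole components to zero
    recon0 = np.einsum("ir,jr,kr->ijk", *factors)
    scale = (np.sqrt(norm_x2) / max(np.linalg.norm(recon0), 1e-300)) ** (1.0 / 3.0)
    factors = [f * scale for f in factors]
    prev_fit = -np.inf
    converged = False
    reseeds = np.zeros(k, dtype=int)  # cap revivals so low-rank data still converges
    for it in range(max_iter):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            # Khatri-Rao of the other two modes, consistent with unfold order
            kr = _khatri_rao(others[0], others[1])
            G = (others[0].T @ others[0]) * (others[1].T @ others[1])  # (k, k)
            M = unfolds[mode] @ kr  # (d_mode, k)
            F = factors[mode]
            col_scale = np.sqrt(np.sqrt(norm_x2) / max(np.prod(dims) ** 0.5, 1.0))
            for r in range(k):
                denom = G[r, r]
                if denom < 1e-14 * max(G.max(), 1.0):
                    if reseeds[r] < 5:
                        # dead component: revive at a data-scaled magnitude
                        F[:, r] = rng.uniform(0.1, 1.0, size=F.shape[0]) * col_scale
                        reseeds[r] += 1
                    continue
                upd = F[:, r] + (M[:, r] - F @ G[:, r]) / denom
                upd = np.maximum(upd, 0.0)
                if not np.any(upd > 0) and reseeds[r] < 5:
                    upd = rng.uniform(0.1, 1.0, size=F.shape[0]) * col_scale
                    reseeds[r] += 1
                F[:, r] = upd
        # fit via cross-products of the last updated mode
        A = factors[0]
        kr = _khatri_rao(factors[1], factors[2])
        G = (factors[1].T @ factors[1]) * (factors[2].T @ factors[2])
        M = unfolds[0] @ kr
        err2 = norm_x2 - 2.0 * float(np.sum(M * A)) + float(np.sum((A.T @ A) * G))
        fit = 100.0 * (1.0 - max(err2, 0.0) / norm_x2)
        if it > 0 and abs(fit - prev_fit) < tol * 100.0:
            converged = True
            prev_fit = fit
            break
        prev_fit = fit
    return factors, prev_fit, converged


def parafac_fit(
    tensor: np.ndarray | WeightTensor,
    k: int,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> ComponentSet:
    """Non-negative PARAFAC by HALS with random restarts; best fit kept.

    Components are reordered by descending explained variation (norm of
    the rank-1 term). Deterministic under a fixed seed. Raises when no
    restart converges.
    """
    x = tensor.data if isinstance(tensor, WeightTensor) else np.asarray(tensor, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected a 3-way array")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    best: tuple[list[np.ndarray], float] | None = None
    any_converged = False
    for r in range(n_restarts):
        factors, fit, conv = _hals_once(x, k, rng, tol, max_iter)
        any_converged = any_converged or conv
        if best is None or fit > best[1]:
            best = (factors, fit)
    if not any_converged:
        raise RuntimeError(
            f"non-negative PARAFAC did not converge in any of {n_restarts} restarts "
            f"(k={k}, best fit {best[1]:.3f}%)"
        )
    factors, fit = best
    strength = np.array([
        np.linalg.norm(factors[0][:, r]) * np.linalg.norm(factors[1][:, r])
        * np.linalg.norm(factors[2][:, r])
        for r in range(k)
    ])
    order = np.argsort(-strength)
    factors = [f[:, order] for f in factors]
    return ComponentSet(factors=factors, fit_pct=float(fit), k=k)


def core_consistency(
    tensor: np.ndarray | WeightTensor, comp: ComponentSet
) -> float:
    """Core consistency diagnostic (percent; 100 = perfect trilinearity).

    The least-squares Tucker core G given the PARAFAC loadings is compared
    to the superdiagonal array T of ones:
    CCD = 100 (1 - sum (G - T)^2 / sum T^2).
    """
    x = tensor.data if isinstance(tensor, WeightTensor) else np.asarray(tensor, dtype=float)
    k = comp.k
    pinvs = [np.linalg.pinv(f) for f in comp.factors]
    g = np.einsum("ia,jb,kc,abc->ijk", pinvs[0], pinvs[1], pinvs[2], x, optimize=True)
    t = np.zeros((k, k, k))
    for r in range(k):
        t[r, r, r] = 1.0
    return float(100.0 * (1.0 - np.sum((g - t) ** 2) / k))


def select_components(
    tensor: np.ndarray | WeightTensor,
    k_max: int = 6,
    ccd_threshold: float = 40.0,
    n_restarts: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame, dict[int, ComponentSet]]:
    """Largest component number whose core consistency stays above threshold.

    Fits the model afresh at every k in 1..k_max and returns
    (k_star, diagnostics table, fitted models). When no k satisfies the
    rule, k_star = 1 with a warning.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    rows = []
    models: dict[int, ComponentSet] = {}
    for k in range(1, k_max + 1):
        comp = parafac_fit(tensor, k, n_restarts=n_restarts, seed=seed + k, **fit_kwargs)
        comp.ccd_pct = core_consistency(tensor, comp)
        models[k] = comp
        rows.append({"k": k, "fit_pct": comp.fit_pct, "ccd_pct": comp.ccd_pct})
    table = pd.DataFrame(rows)
    ok = table[table["ccd_pct"] > ccd_threshold]["k"]
    if ok.empty:
        log.warning("no component number keeps CCD above %.0f%%; falling back to k=1",
                    ccd_threshold)
        return 1, table, models
    return int(ok.max()), table, models


# ---------------------------------------------------------------------------
# Derived summaries


def frequency_peak(freq_scores: np.ndarray, freqs: np.ndarray) -> float:
    """Grid frequency at the maximal score; ties resolved to the lowest."""
    freq_scores = np.asarray(freq_scores, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.allclose(freq_scores, freq_scores[0]):
        raise ValueError("flat frequency scores have no peak")
    peak = freqs[int(np.argmax(freq_scores))]  # argmax takes the first = lowest
    if np.sum(freq_scores == freq_scores.max()) > 1:
        log.info("frequency peak tie broken to the lowest frequency (%.0f Hz)", peak)
    return float(peak)


def region_scores(
    space_scores: np.ndarray,
    axis3: list[Axis3Entry],
    region_of: dict[str, str],
    regions: list[str],
) -> dict[tuple[str, str], pd.DataFrame]:
    """Directed region x region score matrices, per (dataset, state).

    Entry (A, B) sums the electrode-pair scores whose source electrode lies
    in region A and destination in region B.
    """
    space_scores = np.asarray(space_scores, dtype=float)
    if space_scores.shape[0] != len(axis3):
        raise ValueError("score length does not match axis map")
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for score, e in zip(space_scores, axis3):
        if e.src not in region_of or e.dst not in region_of:
            raise ValueError(f"unmapped electrode in axis entry {e}")
        key = (e.dataset, e.state)
        if key not in out:
            out[key] = pd.DataFrame(0.0, index=regions, columns=regions)
        out[key].loc[region_of[e.src], region_of[e.dst]] += score
    return out


def average_region_scores(
    per_dataset: dict[tuple[str, str], pd.DataFrame]
) -> dict[str, pd.DataFrame]:
    """Mean of the per-dataset region matrices, one matrix per state."""
    by_state: dict[str, list[pd.DataFrame]] = {}
    for (_, state), m in per_dataset.items():
        by_state.setdefault(state, []).append(m)
    return {s: sum(ms) / len(ms) for s, ms in by_state.items()}


def directional_difference(m: pd.DataFrame) -> pd.DataFrame:
    """M - M^T: net directed interaction per region pair (antisymmetric)."""
    return m - m.T


def electrode_flow(
    space_scores: np.ndarray,
    axis3: list[Axis3Entry],
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-electrode total interaction and net outflow, per (dataset, state).

    total(e) sums scores of pairs where e is source or destination;
    net(e) = outflow - inflow. The nets sum to zero over electrodes.
    """
    space_scores = np.asarray(space_scores, dtype=float)
    acc: dict[tuple[str, str], dict[str, list[float]]] = {}
    for score, e in zip(space_scores, axis3):
        key = (e.dataset, e.state)
        d = acc.setdefault(key, {})
        for ch, sgn in ((e.src, +1.0), (e.dst, -1.0)):
            rec = d.setdefault(ch, [0.0, 0.0])
            rec[0] += score
            rec[1] += sgn * score
    out = {}
    for key, d in acc.items():
        df = pd.DataFrame(
            [(ch, v[0], v[1]) for ch, v in sorted(d.items())],
            columns=["electrode", "total", "net"],
        ).set_index("electrode")
        out[key] = df
    return out


def spatial_frequency_correlation(
    freq_x: np.ndarray, space_x: np.ndarray,
    freq_y: np.ndarray, space_y: np.ndarray,
) -> float:
    """Similarity of two components in frequency and electrode-pair space.

    R_f and R_s are Spearman rank correlations of the frequency scores and
    of the electrode-pair scores; the combined statistic is their product
    R_f * R_s — symmetric, in [-1, 1], and equal to the single-axis rank
    correlation when the other axis matches perfectly.
    """
    for v in (freq_x, space_x, freq_y, space_y):
        if np.std(v) == 0:
            raise ValueError("zero-variance score vector: correlation undefined")
    if len(freq_x) != len(freq_y) or len(space_x) != len(space_y):
        raise ValueError("axis length mismatch")
    r_f = spearmanr(freq_x, freq_y).statistic
    r_s = spearmanr(space_x, space_y).statistic
    return float(r_f * r_s)


def individual_consistency(
    matrices: dict[str, dict[tuple[int, str], pd.DataFrame]],
    alpha: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """Ratio of dataset pairs with significantly correlated region matrices.

    ``matrices`` maps dataset -> {(component, state) -> region matrix}.
    For every (component, state) and every pair of datasets, the Spearman
    correlation of the flattened matrices is tested; p-values are
    Benjamini-Hochberg corrected across all tests, and the ratio of
    significant dataset pairs is returned together with the full table.
    """
    datasets = sorted(matrices)
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    keys = sorted(matrices[datasets[0]])
    rows = []
    for comp_state in keys:
        for da, db in combinations(datasets, 2):
            a = matrices[da][comp_state].to_numpy().ravel()
            b = matrices[db][comp_state].to_numpy().ravel()
            if np.std(a) == 0 or np.std(b) == 0:
                log.warning("constant region matrix in %s/%s: counted non-significant",
                            da if np.std(a) == 0 else db, comp_state)
                rho, p = 0.0, 1.0
            else:
                res = spearmanr(a, b)
                rho, p = float(res.statistic), float(res.pvalue)
            rows.append({"component": comp_state[0], "state": comp_state[1],
                         "dataset_a": da, "dataset_b": db, "rho": rho, "p_value": p})
    table = pd.DataFrame(rows)
    rej, p_adj, _, _ = multipletests(table["p_value"], alpha=alpha, method="fdr_bh")
    table["p_adjusted"] = p_adj
    table["significant"] = rej
    return float(np.mean(rej)), table


# ---------------------------------------------------------------------------
# Component matching helpers


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient: cosine of the two score vectors."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector has no congruence")
    return float(np.dot(a, b) / (na * nb))


def match_components(
    true_factors: list[np.ndarray], est_factors: list[np.ndarray]
) -> tuple[tuple[int, ...], np.ndarray]:
    """Best permutation matching estimated to true components (brute force).

    Maximizes the summed product of per-mode congruences; returns the
    permutation (est column for each true column) and, per true component,
    the minimum congruence across the three modes under that matching.
    Scale indeterminacy is handled by the congruence itself (scale-free).
    """
    k = true_factors[0].shape[1]
    best_perm, best_score = None, -np.inf
    for perm in permutations(range(k)):
        score = 0.0
        for r, pr in enumerate(perm):
            score += np.prod([
                tucker_congruence(f[:, r], g[:, pr])
                for f, g in zip(true_factors, est_factors)
            ])
        if score > best_score:
            best_perm, best_score = perm, score
    cong = np.array([
        min(
            tucker_congruence(f[:, r], g[:, best_perm[r]])
            for f, g in zip(true_factors, est_factors)
        )
        for r in range(k)
    ])
    return best_perm, cong


def state_dominance(
    space_scores: np.ndarray, axis3: list[Axis3Entry]
) -> tuple[str, float]:
    """Which state carries a component: the one with the larger score mass.

    Returns (state, fraction of total score mass in that state).
    """
    totals: dict[str, float] = {}
    for score, e in zip(np.asarray(space_scores, dtype=float), axis3):
        totals[e.state] = totals.get(e.state, 0.0) + float(score)
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("all-zero component scores")
    state = max(totals, key=totals.get)
    return state, totals[state] / grand
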