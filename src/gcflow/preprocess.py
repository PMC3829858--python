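"""Preprocessing: from raw recordings to condition samples of short bins.

The chain mirrors standard intracranial-electrophysiology practice: bipolar
re-referencing of neighbouring electrodes, anti-aliased downsampling to
200 Hz, multitaper regression removal of 50 Hz line noise per 2-s bin,
robust-amplitude rejection of noisy bins, an optional slow-wave synchrony
gate for sleep data, random disjoint selection of 2-s bins into condition
samples pooled across sessions, and finally subdivision into 200-ms short
bins that are linearly detrended and z-scored per channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import SignalRecord

__all__ = [
    "BinSet",
    "SsiSeries",
    "DegenerateBinError",
    "bipolar_rereference",
    "downsample",
    "remove_line_noise",
    "detrend_zscore",
    "exclude_noisy_bins",
    "compute_ssi",
    "build_condition_samples",
]

log = logging.getLogger(__name__)

#: 2-s analysis bin and 200-ms short bin, in seconds
BIN_SEC = 2.0
SHORT_BIN_SEC = 0.2
#: short bins per 2-s bin
SHORT_PER_BIN = int(round(BIN_SEC / SHORT_BIN_SEC))


class DegenerateBinError(ValueError):
    """A short bin whose residual after linear detrend has zero variance."""


@dataclass
class BinSet:
    """One condition sample: z-scored 200-ms short bins (pseudo-trials).

    ``bins`` has shape (n_short, n_channels, samples_per_short); with the
    default geometry one condition sample holds 600 short bins = 120 s.
    ``parent_bins`` records, per short bin, the (session, 2-s bin index)
    it came from.
    """

    bins: np.ndarray
    parent_bins: list[tuple[str, int]]
    condition_sample_id: int
    state: str
    channels: list[str]
    region_of: dict[str, str]
    rate: float = 200.0

    @property
    def n_short(self) -> int:
        return self.bins.shape[0]

    def pair_trials(self, ch_i: int, ch_j: int) -> np.ndarray:
        """Trials restricted to an (ordered) channel pair: (n_short, 2, m)."""
        return self.bins[:, [ch_i, ch_j], :]


@dataclass
class SsiSeries:
    """Spatial synchronization index, one scalar per 2-s bin."""

    values: np.ndarray
    threshold: float = 0.25

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite SSI values")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")

    def admitted(self) -> np.ndarray:
        return self.values > self.threshold


# ---------------------------------------------------------------------------


def bipolar_rereference(
    record: SignalRecord, pairing: list[tuple[int, int]]
) -> SignalRecord:
    """Difference of nearest-neighbour electrode pairs as local activity.

    Each original electrode may be used only once, so the output channel
    count is half the input's. Unpaired electrodes are dropped with a
    warning. The derived channel inherits the first electrode's region.
    """
    used: set[int] = set()
    for a, b in pairing:
        if a == b or a in used or b in used:
            raise ValueError(f"electrode reused or self-paired in ({a}, {b})")
        used.update((a, b))
    n_in = record.n_channels
    if any(i < 0 or i >= n_in for pair in pairing for i in pair):
        raise ValueError("pairing index out of range")
    leftover = set(range(n_in)) - used
    if leftover:
        log.warning("bipolar_rereference: dropping %d unpaired electrodes", len(leftover))
    out = np.empty((len(pairing), record.n_samples))
    names, region_of = [], {}
    for k, (a, b) in enumerate(pairing):
        out[k] = record.samples[a] - record.samples[b]
        name = f"{record.channels[a]}-{record.channels[b]}"
        names.append(name)
        region_of[name] = record.region_of[record.channels[a]]
    return SignalRecord(
        samples=out,
        rate=record.rate,
        channels=names,
        region_of=region_of,
        state=record.state,
        session=record.session,
    )


def downsample(record: SignalRecord, target_rate: float) -> SignalRecord:
    """Anti-alias low-pass then decimate to ``target_rate``.

    The low-pass is an 8th-order zero-phase Butterworth with cutoff at 0.8
    of the target Nyquist (80 Hz for a 200 Hz target), protecting the
    6–100 Hz analysis band.
    """
    q = record.rate / target_rate
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"target rate {target_rate} does not divide source rate {record.rate}")
    q = int(round(q))
    if q == 1:
        return record
    cutoff = 0.4 * target_rate  # 0.8 x target Nyquist
    sos = sps.butter(8, cutoff, btype="low", fs=record.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, record.samples, axis=1)
    out = filtered[:, ::q]
    return SignalRecord(
        samples=out,
        rate=target_rate,
        channels=list(record.channels),
        region_of=dict(record.region_of),
        state=record.state,
        session=record.session,
    )


def remove_line_noise(
    bin2s: np.ndarray, f0: float = 50.0, rate: float = 200.0, nw: float = 3.0
) -> np.ndarray:
    """Regress a sinusoid at ``f0`` out of one 2-s bin via multitaper estimate.

    The complex amplitude at the line frequency is estimated with Slepian
    (DPSS) tapers in Thomson's harmonic-regression style and the fitted
    sinusoid is subtracted; bands away from ``f0`` are essentially untouched.
    """
    bin2s = np.asarray(bin2s, dtype=float)
    n = bin2s.shape[-1]
    if f0 >= rate / 2.0:
        raise ValueError(f"line frequency {f0} Hz is at or above Nyquist ({rate / 2} Hz)")
    k_tapers = int(2 * nw - 1)
    tapers = sps.windows.dpss(n, nw, Kmax=k_tapers)  # (K, n)
    t = np.arange(n)
    e = np.exp(-2j * np.pi * f0 * t / rate)
    # eigencoefficients of the data and of a unit DC signal at f0
    J = (tapers[None, :, :] * bin2s[:, None, :] * e[None, None, :]).sum(axis=-1)  # (C, K)
    H0 = tapers.sum(axis=1)  # (K,)
    mu = (J @ H0) / (H0 @ H0)  # complex amplitude per channel
    fitted = 2.0 * np.real(mu[:, None] * np.conj(e)[None, :])
    return bin2s - fitted


def detrend_zscore(shortbin: np.ndarray) -> np.ndarray:
    """Remove the best-fit line per channel, then z-score to mean 0, sd 1."""
    shortbin = np.asarray(shortbin, dtype=float)
    resid = sps.detrend(shortbin, axis=-1, type="linear")
    sd = resid.std(axis=-1, keepdims=True)
    if np.any(sd < 1e-12):
        raise DegenerateBinError("zero residual variance after linear detrend")
    out = resid / sd
    return out - out.mean(axis=-1, keepdims=True)


def exclude_noisy_bins(
    bins2s: np.ndarray, amplitude_z_max: float = 5.0
) -> tuple[np.ndarray, list[int]]:
    """Reject 2-s bins with extreme amplitudes; returns (kept indices, rejected).

    A bin is rejected when any channel's absolute deviation from its
    session-wide median exceeds ``amplitude_z_max`` robust standard
    deviations (1.4826 x median absolute deviation).
    """
    bins2s = np.asarray(bins2s, dtype=float)
    n_bins, n_ch, _ = bins2s.shape
    flat = bins2s.transpose(1, 0, 2).reshape(n_ch, -1)
    med = np.median(flat, axis=1)
    mad = np.median(np.abs(flat - med[:, None]), axis=1)
    robust_sd = 1.4826 * mad
    robust_sd[robust_sd == 0] = np.inf
    dev = np.abs(bins2s - med[None, :, None]) / robust_sd[None, :, None]
    bad = np.any(dev.reshape(n_bins, -1) > amplitude_z_max, axis=1)
    rejected = list(np.flatnonzero(bad))
    kept = np.flatnonzero(~bad)
    if kept.size == 0:
        raise ValueError("all bins rejected by the amplitude gate")
    return kept, rejected


def compute_ssi(bin2s: np.ndarray, rate: float = 200.0) -> float:
    """Spatial synchronization index of one 2-s bin.

    Mean pairwise Pearson correlation of the 0.5–4 Hz band-passed,
    per-channel-normalized signals: near 1 during cortex-wide slow-wave
    synchrony, near 0 for independent channels. Symmetric in channel order.
    """
    bin2s = np.asarray(bin2s, dtype=float)
    if bin2s.shape[0] < 2:
        raise ValueError("SSI needs at least 2 channels")
    sos = sps.butter(4, [0.5, 4.0], btype="band", fs=rate, output="sos")
    slow = sps.sosfiltfilt(sos, bin2s, axis=1)
    sd = slow.std(axis=1)
    keep = sd > 0
    if keep.sum() < 2:
        return 0.0
    c = np.corrcoef(slow[keep])
    n = c.shape[0]
    return float((c.sum() - n) / (n * (n - 1)))


# ---------------------------------------------------------------------------


def _segment_2s(record: SignalRecord) -> np.ndarray:
    """Cut a record into consecutive non-overlapping 2-s bins (drop remainder)."""
    n_per = int(round(BIN_SEC * record.rate))
    n_bins = record.n_samples // n_per
    return record.samples[:, : n_bins * n_per].reshape(
        record.n_channels, n_bins, n_per
    ).transpose(1, 0, 2)


def build_condition_samples(
    records: list[SignalRecord],
    n_samples: int = 6,
    bins_per_sample: int = 60,
    seed: int = 0,
    amplitude_z_max: float = 5.0,
    ssi_threshold: float | None = None,
    line_hz: float | None = 50.0,
) -> list[BinSet]:
    """Select disjoint condition samples of clean 2-s bins pooled over sessions.

    Every session contributes an equal share of bins to each condition
    sample (remainders distributed deterministically). Selected bins are
    line-noise filtered, cut into 200-ms short bins, and each short bin is
    detrended and z-scored per channel. For sleep data pass an
    ``ssi_threshold`` so that only bins whose synchrony index exceeds it
    are eligible.
    """
    if not records:
        raise ValueError("no records given")
    state = records[0].state
    rate = records[0].rate
    channels = records[0].channels
    for r in records:
        if r.state != state or r.rate != rate or r.channels != channels:
            raise ValueError("records must share state, rate and channel layout")

    rng = np.random.default_rng(seed)
    n_sessions = len(records)
    base, extra = divmod(bins_per_sample, n_sessions)
    share = [base + (1 if s < extra else 0) for s in range(n_sessions)]

    # per session: clean (and optionally SSI-admitted) bin indices, shuffled
    session_bins: list[np.ndarray] = []
    clean_idx: list[np.ndarray] = []
    for rec in records:
        bins = _segment_2s(rec)
        kept, rejected = exclude_noisy_bins(bins, amplitude_z_max)
        if rejected:
            log.info("session %s: rejected 2-s bins %s", rec.session, rejected)
        if ssi_threshold is not None:
            ssi = SsiSeries(
                np.array([compute_ssi(bins[i], rate) for i in kept]),
                threshold=ssi_threshold,
            )
            kept = kept[ssi.admitted()]
        need = n_samples * share[len(session_bins)]
        if kept.size < need:
            raise ValueError(
                f"session {rec.session}: only {kept.size} clean bins available, "
                f"{need} required ({n_samples} samples x {share[len(session_bins)]})"
            )
        order = rng.permutation(kept)
        session_bins.append(bins)
        clean_idx.append(order)

    n_short = int(round(SHORT_BIN_SEC * rate))
    out: list[BinSet] = []
    for s in range(n_samples):
        shorts, parents = [], []
        for sess, rec in enumerate(records):
            lo = s * share[sess]
            chosen = clean_idx[sess][lo : lo + share[sess]]
            for b in sorted(chosen):
                bin2 = session_bins[sess][b]
                if line_hz is not None:
                    bin2 = remove_line_noise(bin2, f0=line_hz, rate=rate)
                for j in range(SHORT_PER_BIN):
                    sb = bin2[:, j * n_short : (j + 1) * n_short]
                    try:
                        shorts.append(detrend_zscore(sb))
                        parents.append((rec.session, int(b)))
                    except DegenerateBinError:
                        log.warning(
                            "degenerate short bin excluded (session %s, bin %d)",
                            rec.session,
                            b,
                        )
        out.append(
            BinSet(
                bins=np.stack(shorts),
                parent_bins=parents,
                condition_sample_id=s,
                state=state,
                channels=list(channels),
                region_of=dict(records[0].region_of),
                rate=rate,
            )
        )
    return out
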