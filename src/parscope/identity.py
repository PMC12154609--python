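"""Collinear X-Y identity: difference counts, sliding-window profiles,
pseudoautosomal-boundary (PAB) detection, homology arcs, and the PAR
recombination-rate calculation.

All comparisons are gap-free and positional: the two sequences must be equal
length and are compared site by site. Only positions where both bases are
ACGT contribute; windows with no comparable bases are flagged missing
(identity = NaN), never reported as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode

PROFILE_COLUMNS = ["window_start", "window_len", "identity", "n_compared"]


@dataclass(frozen=True)
class HomologyArc:
    """A maximal run of high-identity windows (coordinates on the profile)."""

    start: int
    end: int
    mean_identity: float


def _compare(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    ca, cb = encode(a), encode(b)
    valid = (ca < 4) & (cb < 4)
    match = valid & (ca == cb)
    return match, valid


def count_differences(a: str, b: str) -> int:
    """Number of positions where both bases are ACGT and unequal."""
    match, valid = _compare(a, b)
    return int(valid.sum() - match.sum())


def sliding_identity(a: str, b: str, window: int = 1_000, step: int = 1_000) -> pd.DataFrame:
    """Percent identity per window along a collinear alignment.

    Returns a DataFrame with ``window_start``, ``window_len``, ``identity``
    (percent, NaN where nothing is comparable) and ``n_compared``. With
    step == window, the n_compared-weighted window mean equals the global
    identity.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    match, valid = _compare(a, b)
    cm = np.concatenate(([0], np.cumsum(match)))
    cv = np.concatenate(([0], np.cumsum(valid)))
    # trailing bases shorter than one window are not reported
    if len(a) < window:
        starts = np.empty(0, dtype=int)
    else:
        starts = np.arange(0, len(a) - window + 1, step)
    n_match = cm[starts + window] - cm[starts]
    n_comp = cv[starts + window] - cv[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(n_comp > 0, 100.0 * n_match / np.maximum(n_comp, 1), np.nan)
    return pd.DataFrame(
        {
            "window_start": starts.astype(int),
            "window_len": window,
            "identity": ident,
            "n_compared": n_comp.astype(int),
        }
    )


def global_identity(a: str, b: str) -> float:
    """Percent identity over all comparable positions."""
    match, valid = _compare(a, b)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable (ACGT vs ACGT) positions")
    return 100.0 * float(match.sum()) / n


def detect_pab(profile: pd.DataFrame, threshold: float = 99.9, k_consecutive: int = 5) -> int | None:
    """Locate the pseudoautosomal boundary on an identity profile.

    Scanning from the telomeric end of the PAR (the start of the profile),
    returns the window_start of the first window of the first run of at least
    ``k_consecutive`` windows with identity strictly below ``threshold``;
    ``None`` if no such run exists (fully pseudoautosomal input). Windows with
    missing identity break runs.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    prof = profile.sort_values("window_start")
    run_start = None
    run_len = 0
    for start, ident in zip(prof["window_start"], prof["identity"]):
        below = bool(np.isfinite(ident) and ident < threshold)
        if below:
            if run_len == 0:
                run_start = int(start)
            run_len += 1
            if run_len >= k_consecutive:
                return run_start
        else:
            run_len = 0
    return None


def homology_arcs(
    profile: pd.DataFrame, threshold: float = 95.0, min_len: int = 0
) -> list[HomologyArc]:
    """Maximal merged runs of windows with identity strictly above ``threshold``
    and total length >= ``min_len``; mean identity is n_compared-weighted."""
    prof = profile.sort_values("window_start")
    arcs: list[HomologyArc] = []
    cur: list[tuple[int, int, float, int]] = []

    def flush() -> None:
        if not cur:
            return
        start = cur[0][0]
        end = cur[-1][0] + cur[-1][1]
        if end - start >= min_len:
            wsum = sum(n for *_x, n in cur)
            mean = sum(i * n for _s, _w, i, n in cur) / wsum if wsum else float("nan")
            arcs.append(HomologyArc(start, end, mean))
        cur.clear()

    prev_end = None
    for start, wlen, ident, n in zip(
        prof["window_start"], prof["window_len"], prof["identity"], prof["n_compared"]
    ):
        passing = bool(np.isfinite(ident) and ident > threshold)
        contiguous = prev_end is None or start <= prev_end
        if passing and (not cur or contiguous):
            cur.append((int(start), int(wlen), float(ident), int(n)))
        else:
            flush()
            if passing:
                cur.append((int(start), int(wlen), float(ident), int(n)))
        prev_end = int(start) + int(wlen)
    flush()
    return arcs


def par_recombination_rate(par_length_bp: int) -> float:
    """Sex-averaged male recombination rate implied by one obligate crossover
    (50 cM) per male meiosis over a PAR of the given length, in cM/Mb.

    A 300-kb PAR gives 50 / 0.3 = 166.67, conventionally quoted truncated
    as ~166 cM/Mb.
    """
    if par_length_bp <= 0:
        raise ValueError("par_length_bp must be positive")
    return 50.0 / (par_length_bp / 1e6)


def write_profile(profile: pd.DataFrame, path) -> None:
    """TSV: ``start window identity n_compared``."""
    out = profile.rename(columns={"window_start": "start", "window_len": "window"})
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")
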