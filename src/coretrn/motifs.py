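"""Motif activity analysis: posterior PWM site counts in promoter windows
and per-sample motif activities from a regularized linear model.

The expected number of binding sites ``N[p, m]`` of motif *m* in the
promoter window of probe *p* (the 400-bp window from -300 to +100 around
the transcript 5' end) is the sum over offsets and strands of the
posterior probability of a site,

    post = prior * L_pwm / (prior * L_pwm + (1 - prior) * L_bg),

with a small prior (1e-5 by default), the PWM likelihood from the
pseudocounted, normalized count matrix, and a 0-order background model.
This is the single-sequence core of posterior-odds motif scanning
(no phylogenetic averaging).

Per-sample motif activities ``A[m, s]`` then solve the ridge-regularized
linear model of log2 promoter expression

    e[p, s] = c_p + sum_m N[p, m] * A[m, s] + noise,

with the per-promoter intercept removed by centering expression across
samples, columns of N centered across promoters, and each motif's fitted
activities centered across samples (sum_s A[m, s] = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "PWM",
    "PromoterWindow",
    "MotifActivityProfile",
    "scan_pwm_posterior",
    "build_site_count_matrix",
    "fit_motif_activities",
    "compare_motif_activities",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """A position count matrix (L x 4, columns A, C, G, T).

    ``probabilities`` adds ``pseudocount`` to every cell and normalizes
    each position row.  SwissRegulon-style matrices are raw counts, hence
    the default pseudocount of 0.5.
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4 or self.counts.shape[0] < 1:
            raise ValueError("PWM counts must be an L x 4 matrix with L >= 1")
        if (self.counts < 0).any():
            raise ValueError("PWM counts must be non-negative")
        if np.any((self.counts + self.pseudocount).sum(axis=1) <= 0):
            raise ValueError("every PWM position must have positive total weight")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        padded = self.counts + self.pseudocount
        return padded / padded.sum(axis=1, keepdims=True)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probabilities.argmax(axis=1))


@dataclass
class PromoterWindow:
    """Promoter sequence of one probe, covering the half-open window
    [-300, +100) relative to the transcript 5' end."""

    probe_id: str
    sequence: str
    window: tuple[int, int] = (-300, 100)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-nucleotide symbols: {sorted(bad)}")
        if len(self.sequence) > self.window[1] - self.window[0]:
            raise ValueError("sequence longer than the promoter window")


@dataclass
class MotifActivityProfile:
    """Fitted motif activities: motifs x samples, centered per motif."""

    activities: pd.DataFrame
    regularization: float
    intercepts: pd.Series | None = field(default=None)

    def sample_activities(self, motif: str) -> pd.Series:
        if motif not in self.activities.index:
            raise KeyError(f"motif {motif!r} not in profile")
        return self.activities.loc[motif]


def _seq_likelihoods(seq: str, probs: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset PWM and background likelihoods of ``seq`` windows.

    Positions holding N contribute the background likelihood to both terms
    (so an all-N window has likelihood ratio exactly 1)."""
    L = probs.shape[0]
    n = len(seq)
    if n < L:
        return np.empty(0), np.empty(0)
    codes = np.array([_BASE_INDEX.get(b, -1) for b in seq])
    # An N contributes its (unknown) background likelihood to both the PWM
    # and the background term; the common factor cancels in the posterior,
    # so both sides use 1.0 at N positions.
    bg_per_pos = np.where(codes >= 0, background[np.clip(codes, 0, 3)], 1.0)
    n_off = n - L + 1
    lp = np.ones(n_off)
    lb = np.ones(n_off)
    for k in range(L):
        window_codes = codes[k : k + n_off]
        lp *= np.where(window_codes >= 0, probs[k, np.clip(window_codes, 0, 3)], 1.0)
        lb *= bg_per_pos[k : k + n_off]
    return lp, lb


def scan_pwm_posterior(
    window: PromoterWindow,
    pwm: PWM,
    prior: float = 1e-5,
    background: np.ndarray | None = None,
    both_strands: bool = True,
) -> float:
    """Expected number of binding sites in one promoter window.

    Sums, over every offset (and both strands by default), the posterior
    probability that a site starts there given the PWM likelihood, the
    0-order background likelihood and the site ``prior``.
    """
    if not 0.0 <= prior < 1.0:
        raise ValueError("prior must lie in [0, 1)")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or not np.isclose(background.sum(), 1.0):
        raise ValueError("background must be 4 base frequencies summing to 1")
    if prior == 0.0:
        return 0.0
    if len(window.sequence) < len(pwm):
        warnings.warn(
            f"window {window.probe_id!r} shorter than PWM {pwm.name!r}; count is 0",
            stacklevel=2,
        )
        return 0.0
    probs = pwm.probabilities
    strands = [window.sequence]
    if both_strands:
        strands.append(window.sequence.translate(_COMPLEMENT)[::-1])
    total = 0.0
    for seq in strands:
        lp, lb = _seq_likelihoods(seq, probs, background)
        post = prior * lp / (prior * lp + (1.0 - prior) * lb)
        total += float(post.sum())
    return total


def build_site_count_matrix(
    windows: list[PromoterWindow],
    pwms: list[PWM],
    prior: float = 1e-5,
    background: np.ndarray | None = None,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Expected site counts for every promoter x motif pair.

    Promoters with an empty sequence get a zero row (flagged by warning).
    Returns a DataFrame indexed by probe_id with one column per motif.
    """
    if not windows or not pwms:
        raise ValueError("windows and pwms must be non-empty")
    ids = [w.probe_id for w in windows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate probe_ids in promoter windows")
    data = np.zeros((len(windows), len(pwms)))
    for i, w in enumerate(windows):
        if not w.sequence:
            warnings.warn(f"promoter {w.probe_id!r} has no sequence; zero row", stacklevel=2)
            continue
        for j, m in enumerate(pwms):
            data[i, j] = scan_pwm_posterior(
                w, m, prior=prior, background=background, both_strands=both_strands
            )
    return pd.DataFrame(data, index=pd.Index(ids, name="probe_id"), columns=[m.name for m in pwms])


def _gcv_lambda(M: np.ndarray, Y: np.ndarray) -> float:
    """Pick ridge lambda by generalized cross-validation on an SVD grid."""
    u, s, _ = np.linalg.svd(M, full_matrices=False)
    uty = u.T @ Y  # (r, n_samples)
    n = M.shape[0]
    grid = np.concatenate([[1e-8], np.geomspace(1e-6, 1e4, 41)])
    best_lam, best_score = grid[0], np.inf
    y_norm2 = (Y**2).sum(axis=0)
    for lam in grid:
        shrink = s**2 / (s**2 + lam)  # hat-matrix eigenvalues
        resid2 = np.maximum(y_norm2 - (2 * shrink[:, None] * uty**2 - (shrink**2)[:, None] * uty**2).sum(axis=0), 0.0)
        df = shrink.sum()
        denom = (n - df) ** 2
        score = float(np.sum(resid2) / denom) if denom > 0 else np.inf
        if score < best_score:
            best_score, best_lam = score, lam
    return float(best_lam)


def fit_motif_activities(
    expr: ExpressionMatrix,
    site_counts: pd.DataFrame,
    regularization: float | None = None,
) -> MotifActivityProfile:
    """Fit per-sample motif activities by ridge regression.

    ``expr`` holds log2 expression (promoters x samples) aligned row-wise
    with ``site_counts`` (promoters x motifs).  Per-promoter intercepts are
    removed by centering expression across samples; a per-sample offset is
    absorbed by centering expression and the site-count columns across
    promoters.  With ``regularization=None`` lambda is chosen by
    generalized cross-validation.  Motifs whose (centered) site-count
    column is identically zero get activity 0 with a warning.
    """
    if not expr.values.index.equals(site_counts.index):
        raise ValueError("expression rows and site-count rows must be aligned")
    lam = regularization
    if lam is not None and lam < 0:
        raise ValueError("regularization must be non-negative")
    E = expr.values.to_numpy(dtype=float)
    N = site_counts.to_numpy(dtype=float)

    intercepts = E.mean(axis=1)
    Ec = E - intercepts[:, None]          # remove per-promoter intercept
    Ec = Ec - Ec.mean(axis=0, keepdims=True)  # absorb per-sample offset
    M = N - N.mean(axis=0, keepdims=True)

    dead = np.all(M == 0.0, axis=0)
    if dead.any():
        names = list(site_counts.columns[dead])
        warnings.warn(f"zero-variance site-count columns set to activity 0: {names}", stacklevel=2)
    if lam is None:
        lam = _gcv_lambda(M[:, ~dead], Ec) if (~dead).any() else 0.0

    A = np.zeros((N.shape[1], E.shape[1]))
    if (~dead).any():
        Ma = M[:, ~dead]
        gram = Ma.T @ Ma + lam * np.eye(Ma.shape[1])
        if lam == 0.0:
            sol = np.linalg.pinv(Ma) @ Ec
        else:
            sol = np.linalg.solve(gram, Ma.T @ Ec)
        A[~dead, :] = sol
    A = A - A.mean(axis=1, keepdims=True)  # center each motif across samples
    activities = pd.DataFrame(A, index=site_counts.columns, columns=expr.values.columns)
    return MotifActivityProfile(
        activities=activities,
        regularization=float(lam),
        intercepts=pd.Series(intercepts, index=expr.values.index),
    )


def compare_motif_activities(
    profile_a: MotifActivityProfile,
    profile_b: MotifActivityProfile,
    motif: str,
) -> tuple[float, float]:
    """Mean activity difference (A - B) for one motif and the two-sided
    t-test p-value across replicate samples."""
    xa = profile_a.sample_activities(motif).to_numpy(dtype=float)
    xb = profile_b.sample_activities(motif).to_numpy(dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need at least two replicate samples per condition")
    diff = float(xa.mean() - xb.mean())
    _, p = stats.ttest_ind(xa, xb, equal_var=False)
    if np.isnan(p):
        p = 1.0
    return diff, float(p)
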