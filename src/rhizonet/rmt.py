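"""Random-matrix-theory selection of the correlation (similarity) threshold St.

A co-occurrence network needs a cutoff on the OTU-OTU correlation matrix.
Rather than picking one by hand, the threshold is chosen from the spectral
statistics of the thresholded matrix: the nearest-neighbor spacing
distribution (NNSD) of its unfolded eigenvalues.  A matrix dominated by
sampling noise behaves like a Gaussian orthogonal ensemble (GOE) member and
its NNSD follows the Wigner surmise, P(d) = (pi d / 2) exp(-pi d^2 / 4);
once the threshold removes the noise and leaves (near-)independent blocks of
genuine co-variation, the NNSD crosses over to the Poisson form,
P(d) = exp(-d).  St is the smallest scanned threshold at which a chi-square
goodness-of-fit test no longer rejects the Poisson form, persistently over a
small window of consecutive candidates.

Unfolding maps eigenvalues onto a scale where the mean spacing is one, by
fitting a smooth monotone approximation to the empirical cumulative spectral
function.  The default is a monotone piecewise-cubic (PCHIP) interpolant
through a decimated set of CDF points, which adapts to the strongly
multimodal spectra of thresholded correlation matrices (a cluster of
near-zero eigenvalues from rank deficiency at 12 samples plus isolated
large block eigenvalues); a global polynomial fit is available as an
alternative but cannot track such clustered densities.  Degenerate
eigenvalues (e.g. the unit eigenvalues of rows left with no off-diagonal
entries) carry no spacing information and are collapsed before unfolding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .abundance import AbundanceTable

MIN_EIGENVALUES = 20


@dataclass
class CorrelationMatrix:
    """Symmetric OTU x OTU correlation matrix with unit diagonal."""

    otu_ids: list[str]
    values: np.ndarray
    method: str = "pearson"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.otu_ids):
            raise ValueError("correlation matrix shape does not match otu_ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass
class ThresholdScan:
    """Audit record of an St scan: one row per evaluated candidate."""

    records: pd.DataFrame  # columns: st, n_eigen, chi2_poisson, p_poisson, chi2_goe, p_goe
    selected_st: float
    alpha: float
    window: int


def correlation_matrix(table: AbundanceTable, method: str = "pearson") -> CorrelationMatrix:
    """Pearson (or Spearman) correlation of every OTU pair across samples.

    Constant rows carry no correlation signal and are dropped with a warning.
    """
    if table.n_samples < 3:
        raise ValueError(f"need at least 3 samples for correlation, got {table.n_samples}")
    if table.n_otus < 2:
        raise ValueError("need at least 2 OTUs")
    values = table.values.to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    if constant.any():
        import warnings

        dropped = [otu for otu, c in zip(table.otu_ids, constant) if c]
        warnings.warn(f"dropping {len(dropped)} constant OTU rows: {dropped[:5]}...")
        values = values[~constant]
    otu_ids = [otu for otu, c in zip(table.otu_ids, constant) if not c]
    if method == "pearson":
        corr = np.corrcoef(values)
    elif method == "spearman":
        corr = stats.spearmanr(values, axis=1).statistic
        if np.isscalar(corr):  # two rows: spearmanr returns a scalar
            corr = np.array([[1.0, corr], [corr, 1.0]])
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(otu_ids=otu_ids, values=corr, method=method)


def threshold_matrix(corr: CorrelationMatrix, st: float) -> np.ndarray:
    """Zero all off-diagonal entries with |r| < st; diagonal kept."""
    out = corr.values.copy()
    mask = np.abs(out) < st
    np.fill_diagonal(mask, False)
    out[mask] = 0.0
    return out


def _distinct_eigenvalues(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Eigenvalues of the active submatrix, with degenerate values collapsed.

    Rows with no off-diagonal entries contribute exact unit eigenvalues that
    would pile up as zero spacings; they are removed before decomposition,
    and any remaining eigenvalues closer than ``tol`` are merged.
    """
    off = matrix.copy()
    np.fill_diagonal(off, 0.0)
    active = np.abs(off).sum(axis=1) > 0
    sub = matrix[np.ix_(active, active)]
    if sub.shape[0] == 0:
        return np.array([])
    eig = np.linalg.eigvalsh(sub)
    keep = np.concatenate([[True], np.diff(eig) > tol])
    return eig[keep]


def unfold_spectrum(
    eigenvalues: np.ndarray,
    method: str = "spline",
    knot_every: int = 10,
    degree: int = 5,
) -> np.ndarray:
    """Unfold a spectrum so the mean nearest-neighbor spacing is one.

    ``method="spline"`` (default) interpolates the empirical cumulative
    spectral function with a monotone PCHIP through every ``knot_every``-th
    eigenvalue; ``method="poly"`` fits a global polynomial of the given
    degree instead.  The result is sorted, which makes the map monotone in
    the input order, and unfolding is invariant to affine transforms of the
    spectrum.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.ndim != 1 or eig.size < MIN_EIGENVALUES:
        raise ValueError(
            f"need at least {MIN_EIGENVALUES} eigenvalues for a reliable NNSD, got {eig.size}"
        )
    if np.any(np.diff(eig) < 0):
        eig = np.sort(eig)
    n = eig.size
    cumulative = np.arange(1, n + 1) - 0.5
    if method == "spline":
        idx = np.unique(np.r_[np.arange(0, n, knot_every), n - 1])
        # knots must be strictly increasing; merge ties left over from dedup
        keep = np.concatenate([[True], np.diff(eig[idx]) > 0])
        fit = PchipInterpolator(eig[idx][keep], cumulative[idx][keep])
    elif method == "poly":
        fit = Polynomial.fit(eig, cumulative, deg=degree)
    else:
        raise ValueError(f"unknown unfolding method {method!r}; use 'spline' or 'poly'")
    return np.sort(fit(eig))


def nnsd_spacings(unfolded: np.ndarray) -> np.ndarray:
    """Nearest-neighbor spacings of an unfolded spectrum."""
    return np.diff(np.sort(unfolded))


def nnsd_gof(spacings: np.ndarray, model: str, n_bins: int = 10, min_expected: float = 2.0):
    """Chi-square goodness of fit of spacings against Poisson or GOE (Wigner).

    Bins are equal-probability under the null model; trailing bins are merged
    until every expected count reaches ``min_expected``.  Returns
    ``(chi2, p_value)``.
    """
    d = np.asarray(spacings, dtype=float)
    if d.size < MIN_EIGENVALUES:
        raise ValueError(f"need at least {MIN_EIGENVALUES} spacings, got {d.size}")
    if np.any(d < 0):
        raise ValueError("spacings must be nonnegative")
    if model == "poisson":
        # CDF 1 - exp(-d): quantile -ln(1 - q)
        edges = -np.log(1.0 - np.arange(1, n_bins) / n_bins)
    elif model == "goe":
        # Wigner surmise CDF 1 - exp(-pi d^2 / 4): quantile sqrt(-4 ln(1-q)/pi)
        edges = np.sqrt(-4.0 * np.log(1.0 - np.arange(1, n_bins) / n_bins) / np.pi)
    else:
        raise ValueError(f"unknown NNSD model {model!r}; use 'poisson' or 'goe'")
    edges = np.concatenate([[0.0], edges, [np.inf]])
    observed = np.histogram(d, bins=edges)[0].astype(float)
    expected = np.full(n_bins, d.size / n_bins)
    while expected.size > 1 and expected[-1] < min_expected:
        expected[-2] += expected[-1]
        observed[-2] += observed[-1]
        expected, observed = expected[:-1], observed[:-1]
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    dof = expected.size - 1
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, p


def select_threshold(
    corr: CorrelationMatrix,
    st_min: float = 0.30,
    st_max: float = 0.99,
    step: float = 0.01,
    alpha: float = 0.05,
    window: int = 2,
    unfold_method: str = "spline",
) -> ThresholdScan:
    """Scan candidate thresholds and pick St by the Poisson-NNSD criterion.

    For each candidate st the matrix is thresholded at |r| >= st, its
    distinct eigenvalues unfolded, and the NNSD tested against the Poisson
    and GOE forms.  St is the smallest candidate whose Poisson fit is not
    rejected (p > alpha) for ``window`` consecutive candidates.  Candidates
    leaving fewer than 20 distinct eigenvalues cannot be evaluated and
    terminate the scan.
    """
    candidates = np.round(np.arange(st_min, st_max + step / 2, step), 10)
    rows = []
    poisson_ps = []
    for st in candidates:
        eig = _distinct_eigenvalues(threshold_matrix(corr, st))
        if eig.size < MIN_EIGENVALUES:
            break
        spac = nnsd_spacings(unfold_spectrum(eig, method=unfold_method))
        chi2_p, p_p = nnsd_gof(spac, "poisson")
        chi2_g, p_g = nnsd_gof(spac, "goe")
        rows.append((st, eig.size, chi2_p, p_p, chi2_g, p_g))
        poisson_ps.append(p_p)
        if len(poisson_ps) >= window:
            tail = poisson_ps[-window:]
            if all(p > alpha for p in tail):
                selected = rows[len(poisson_ps) - window][0]
                records = pd.DataFrame(
                    rows,
                    columns=["st", "n_eigen", "chi2_poisson", "p_poisson", "chi2_goe", "p_goe"],
                )
                records["selected"] = records["st"] == selected
                return ThresholdScan(records=records, selected_st=float(selected), alpha=alpha, window=window)
    raise ValueError(
        "no candidate threshold satisfied the Poisson-NNSD criterion; "
        f"scanned {len(rows)} candidates in [{st_min}, {st_max}] — widen the range "
        "or lower the persistence window"
    )
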