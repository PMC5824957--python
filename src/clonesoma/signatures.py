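"""Trinucleotide spectra and mutational signature analysis.

Builds the 96-class trinucleotide substitution spectrum per clone
(pyrimidine-collapsed, canonical ordering grouped by substitution class),
extracts de novo signatures by KL-divergence non-negative matrix
factorization with multiplicative updates, refits spectra onto a reference
signature panel by non-negative least squares, fits per-signature age
trends, and clusters clones on the first principal components of their
normalized signature contributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls

from .discovery import SomaticCatalog

__all__ = [
    "SPECTRUM_INDEX",
    "Spectrum96",
    "SignatureSet",
    "SignatureAgeFit",
    "build_spectrum",
    "extract_signatures",
    "refit_to_reference",
    "signature_age_trend",
    "cluster_clones",
    "load_reference_signatures",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

#: Canonical 96-class order: substitution class major, then 5' and 3' base.
SPECTRUM_INDEX = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
_INDEX_LOOKUP = {label: i for i, label in enumerate(SPECTRUM_INDEX)}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class Spectrum96:
    """96-class trinucleotide substitution counts for one clone."""

    clone: str
    counts: np.ndarray
    n_unresolvable: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 classes")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(SPECTRUM_INDEX), name=self.clone)


@dataclass
class SignatureSet:
    """Signature profiles with per-clone contributions.

    ``profiles``: 96 x K matrix with probability-vector columns.
    ``contributions``: K x n_clones non-negative matrix on the mutation-count
    scale, so ``profiles @ contributions`` reconstructs the spectra.
    """

    profiles: pd.DataFrame
    contributions: pd.DataFrame
    kind: str  # "de-novo" | "reference-refit"
    objective: float = float("nan")

    def relative_contributions(self) -> pd.DataFrame:
        """Per-clone contribution as a fraction of reconstructed mutations."""
        totals = self.contributions.sum(axis=0)
        return self.contributions / totals.replace(0, np.nan)


@dataclass
class SignatureAgeFit:
    """Per-signature yearly trend with Bonferroni-adjusted p-value."""

    signature: str
    slope: float
    intercept: float
    slope_se: float
    p_raw: float
    p_adjusted: float
    method: str


def spectrum_matrix(spectra: Sequence[Spectrum96]) -> pd.DataFrame:
    """Stack spectra into the 96 x n_clones count matrix."""
    return pd.DataFrame(
        {s.clone: s.counts for s in spectra}, index=list(SPECTRUM_INDEX))


# ---------------------------------------------------------------------------
# Spectrum construction


def context_label(ref: str, alt: str, ctx5: str, ctx3: str) -> str:
    """Canonical 96-class label, collapsing purine refs onto pyrimidines."""
    ref, alt, ctx5, ctx3 = ref.upper(), alt.upper(), ctx5.upper(), ctx3.upper()
    if ref in "GA":
        ref, alt = _revcomp(ref), _revcomp(alt)
        ctx5, ctx3 = _revcomp(ctx3), _revcomp(ctx5)
    return f"{ctx5}[{ref}>{alt}]{ctx3}"


def build_spectrum(catalog: SomaticCatalog | pd.DataFrame,
                   reference: Mapping[str, str],
                   clone: str | None = None) -> Spectrum96:
    """Count accepted SNVs into the 96 trinucleotide substitution classes.

    ``reference`` maps chromosome name to sequence (a plain mapping or a
    pyfaidx-style object).  Variants at contig edges, with non-ACGT context,
    or whose stated ref allele disagrees with the reference sequence are
    excluded and tallied in ``n_unresolvable``.
    """
    if isinstance(catalog, SomaticCatalog):
        snvs = catalog.accepted_snvs()
    else:
        snvs = catalog[(catalog["ref"].str.len() == 1) & (catalog["alt"].str.len() == 1)]
    if clone is not None:
        snvs = snvs[snvs["clone"] == clone]
        name = clone
    else:
        clones = snvs["clone"].unique() if "clone" in snvs else ["catalog"]
        name = clones[0] if len(clones) == 1 else "pooled"

    counts = np.zeros(96)
    unresolvable = 0
    for _, v in snvs.iterrows():
        chrom, pos0 = v["chrom"], int(v["pos"]) - 1
        seq = reference[chrom]
        if pos0 < 1 or pos0 >= len(seq) - 1:
            unresolvable += 1
            continue
        tri = str(seq[pos0 - 1:pos0 + 2]).upper()
        if any(b not in _BASES for b in tri) or tri[1] != v["ref"].upper():
            unresolvable += 1
            continue
        label = context_label(v["ref"], v["alt"], tri[0], tri[2])
        counts[_INDEX_LOOKUP[label]] += 1
    return Spectrum96(clone=name, counts=counts, n_unresolvable=unresolvable)


# ---------------------------------------------------------------------------
# NMF signature extraction


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    WH = np.maximum(WH, 1e-12)
    return float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum())


def _nmf_kl(V: np.ndarray, rank: int, rng: np.random.Generator,
            max_iter: int, tol: float):
    """Multiplicative-update NMF under generalized KL divergence.

    Returns (W, H, objective, per-iteration objective trace).  The
    multiplicative updates are monotone in the objective.
    """
    m, n = V.shape
    scale = np.sqrt(V.mean() / rank)
    W = rng.uniform(0.5, 1.5, size=(m, rank)) * scale
    H = rng.uniform(0.5, 1.5, size=(rank, n)) * scale
    trace = []
    prev = np.inf
    for _ in range(max_iter):
        WH = np.maximum(W @ H, 1e-12)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], 1e-12)
        WH = np.maximum(W @ H, 1e-12)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], 1e-12)
        obj = _kl_divergence(V, W @ H)
        trace.append(obj)
        if prev - obj < tol * max(1.0, abs(prev)):
            break
        prev = obj
    return W, H, trace[-1], trace


def extract_signatures(spectra: pd.DataFrame | Sequence[Spectrum96],
                       rank: int = 3,
                       n_restarts: int = 20,
                       seed: int | None = None,
                       max_iter: int = 2000,
                       tol: float = 1e-9) -> SignatureSet:
    """De novo signature extraction by KL-NMF with random restarts.

    Takes the 96 x n_clones count matrix (or a list of spectra), runs the
    multiplicative-update factorization from ``n_restarts`` random
    initializations, and keeps the solution with the lowest divergence.
    Profile columns are normalized to probability vectors with the scale
    moved into the contributions.  Deterministic under ``seed``.
    """
    if not isinstance(spectra, pd.DataFrame):
        spectra = spectrum_matrix(spectra)
    V = spectra.to_numpy(dtype=float)
    if V.shape[0] != 96:
        raise ValueError("spectra matrix must have 96 rows")
    if (V < 0).any():
        raise ValueError("spectra must be non-negative")
    if not V.sum():
        raise ValueError("cannot extract signatures from an all-zero matrix")
    if V.shape[1] < rank:
        raise ValueError(f"need at least {rank} clones for rank-{rank} extraction")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        W, H, obj, _ = _nmf_kl(V, rank, rng, max_iter, tol)
        if best is None or obj < best[2]:
            best = (W, H, obj)
    W, H, obj = best
    col_sums = np.maximum(W.sum(axis=0), 1e-12)
    W = W / col_sums
    H = H * col_sums[:, None]
    order = np.argsort(-H.sum(axis=1))  # largest overall contribution first
    names = [f"SBS-denovo{i + 1}" for i in range(rank)]
    profiles = pd.DataFrame(W[:, order], index=spectra.index, columns=names)
    contributions = pd.DataFrame(H[order], index=names, columns=spectra.columns)
    return SignatureSet(profiles=profiles, contributions=contributions,
                        kind="de-novo", objective=obj)


def nmf_objective_trace(V: np.ndarray, rank: int, seed: int | None = None,
                        max_iter: int = 200) -> list:
    """Per-iteration KL objective of a single NMF run (diagnostic)."""
    rng = np.random.default_rng(seed)
    *_, trace = _nmf_kl(np.asarray(V, float), rank, rng, max_iter, tol=0.0)
    return trace


def match_profiles(estimated: pd.DataFrame, truth: pd.DataFrame):
    """Hungarian matching of estimated to true profiles by cosine similarity.

    Returns (matching as list of (estimated column, truth column), cosine
    similarities of the matched pairs).
    """
    A = estimated.to_numpy(float)
    B = truth.to_numpy(float)
    A = A / np.maximum(np.linalg.norm(A, axis=0), 1e-12)
    B = B / np.maximum(np.linalg.norm(B, axis=0), 1e-12)
    cos = A.T @ B
    rows, cols = linear_sum_assignment(-cos)
    pairs = [(estimated.columns[r], truth.columns[c]) for r, c in zip(rows, cols)]
    return pairs, cos[rows, cols]


# ---------------------------------------------------------------------------
# Reference refitting


def load_reference_signatures() -> pd.DataFrame:
    """Load the packaged reference signature panel (96 x 30).

    A synthetic panel in the layout of the COSMIC v2 signature matrix,
    generated deterministically for this package (see
    ``scripts/make_reference_signatures.py``); it is not the published
    COSMIC data.  Columns sum to 1.
    """
    path = resources.files("clonesoma.data") / "reference_signatures_synthetic.tsv"
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.reindex(list(SPECTRUM_INDEX))


def refit_to_reference(spectrum: Spectrum96 | np.ndarray,
                       reference_profiles: pd.DataFrame) -> pd.Series:
    """Non-negative least-squares refit of a spectrum onto reference profiles.

    Minimizes ``||spectrum - P c||_2`` subject to ``c >= 0``; the returned
    contributions are on the mutation-count scale.
    """
    v = spectrum.counts if isinstance(spectrum, Spectrum96) else np.asarray(spectrum, float)
    P = reference_profiles.to_numpy(dtype=float)
    if P.shape[0] != v.shape[0]:
        raise ValueError("profile matrix and spectrum dimensions disagree")
    coef, _ = nnls(P, v)
    return pd.Series(coef, index=reference_profiles.columns)


def refit_catalog(spectra: pd.DataFrame,
                  reference_profiles: pd.DataFrame) -> SignatureSet:
    """Refit every clone's spectrum onto the reference panel."""
    contrib = pd.DataFrame(
        {c: refit_to_reference(spectra[c].to_numpy(), reference_profiles)
         for c in spectra.columns})
    return SignatureSet(profiles=reference_profiles.copy(),
                        contributions=contrib, kind="reference-refit")


# ---------------------------------------------------------------------------
# Age trends and clustering


def signature_age_trend(contributions: pd.DataFrame,
                        metadata: pd.DataFrame,
                        n_tested: int = 3,
                        signatures: Sequence[str] | None = None) -> list:
    """Per-signature linear trend of contribution with donor age.

    Fits the robust mixed model from :func:`clonesoma.aging.fit_rate`
    (donor random intercept) per signature and Bonferroni-adjusts the
    p-values for the ``n_tested`` signatures examined.
    """
    from .aging import fit_rate

    if signatures is None:
        signatures = list(contributions.index)[:n_tested]
    meta = metadata.set_index("clone")
    fits = []
    for sig in signatures:
        df = pd.DataFrame({
            "clone": contributions.columns,
            "donor": meta.loc[contributions.columns, "donor"].to_numpy(),
            "age": meta.loc[contributions.columns, "age"].to_numpy(),
            "y": contributions.loc[sig].to_numpy(float),
        })
        fit = fit_rate(df, response="y")
        fits.append(SignatureAgeFit(
            signature=sig, slope=fit.slope, intercept=fit.intercept,
            slope_se=fit.slope_se, p_raw=fit.p_value,
            p_adjusted=min(1.0, n_tested * fit.p_value), method=fit.method))
    return fits


def cluster_clones(contributions: pd.DataFrame,
                   n_pcs: int = 3, k: int = 2,
                   n_perm: int = 100_000,
                   seed: int | None = None,
                   normalization: str = "row_sum") -> dict:
    """PCA + k-means clustering of clones on signature contributions.

    Contributions (signatures x clones) are normalized per clone (row-sum
    by default, z-scaling optional), projected onto the first ``n_pcs``
    principal components, and clustered by k-means run from ``n_perm``
    random initializations, keeping the best within-cluster sum of squares.
    Labels follow a stable convention: cluster 0 is the larger cluster,
    ties broken by the lexicographically smallest member clone id.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    X = contributions.T.to_numpy(dtype=float)  # clones x signatures
    clones = list(contributions.columns)
    if k > len(clones):
        raise ValueError(f"cannot form {k} clusters from {len(clones)} clones")
    if normalization == "row_sum":
        totals = X.sum(axis=1, keepdims=True)
        X = np.divide(X, totals, out=np.zeros_like(X), where=totals > 0)
    elif normalization == "zscore":
        sd = X.std(axis=1, keepdims=True)
        X = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    n_pcs = min(n_pcs, X.shape[1], max(1, X.shape[0] - 1))
    pcs = PCA(n_components=n_pcs, random_state=0).fit_transform(X)

    degenerate = bool(np.allclose(pcs, pcs[0]))
    km = KMeans(n_clusters=k, init="random", n_init=n_perm,
                random_state=np.random.default_rng(seed).integers(2**31))
    labels = km.fit_predict(pcs)

    # stable label convention
    sizes = np.bincount(labels, minlength=k)
    order = sorted(range(k), key=lambda c: (
        -sizes[c],
        min((clones[i] for i in range(len(clones)) if labels[i] == c), default="")))
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[l] for l in labels])
    return {
        "labels": pd.Series(labels, index=clones, name="cluster"),
        "pcs": pd.DataFrame(pcs, index=clones,
                            columns=[f"PC{i + 1}" for i in range(pcs.shape[1])]),
        "inertia": float(km.inertia_),
        "degenerate": degenerate,
    }
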