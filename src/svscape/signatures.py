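"""De-novo SV signature extraction over the 32-channel matrix.

Signatures are extracted by non-negative matrix factorization (NMF) with a
Kullback-Leibler objective, which is the maximum-likelihood factorization
for Poisson-distributed mutation counts.  Stability-based model selection
follows standard signature practice:

* for each candidate rank k, the channel matrix is Poisson-bootstrapped and
  factorized across many replicates;
* replicate signatures are pooled and clustered by partition around medoids
  (PAM) on cosine distance;
* the mean silhouette of that clustering is the stability of rank k, and
  the medoid profiles are the reported signatures;
* the selected k is the largest rank that is stable (silhouette >= 0.80)
  and still improves reconstruction error by more than 1% over k - 1.

Exposures are per-sample non-negative least-squares fits to the fixed
profiles; a per-sample reconstruction cosine guards positivity calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)


def load_reference_catalog(path=None) -> pd.DataFrame:
    """Load a reference signature catalog (signatures x 32 channels).

    The packaged default is a synthetic stand-in whose profiles echo the
    qualitative character of the ten published rearrangement signatures;
    it is not the published catalog.  Profiles are re-normalized on load.
    """
    if path is None:
        from importlib import resources

        ref = resources.files("svscape.assets") / "reference_signatures.synthetic.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df.div(df.sum(axis=1), axis=0)


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two non-negative vectors (0 when either is 0)."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH)."""
    WH = W @ H
    mask = V > 0
    return float(
        np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], 1e-12)))
        - V.sum() + WH.sum()
    )


def _fit_nmf(V: np.ndarray, k: int, seed: int, tol: float, max_iter: int
             ) -> tuple[np.ndarray, np.ndarray, float]:
    """One KL-NMF fit (multiplicative updates); returns (W, H, kl)."""
    model = NMF(
        n_components=k, init="random", solver="mu",
        beta_loss="kullback-leibler", tol=tol, max_iter=max_iter,
        random_state=seed,
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # hitting max_iter at tight tolerance is routine for KL-NMF
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(V)
    H = model.components_
    return W, H, _kl_divergence(V, W, H)


def _pam(X: np.ndarray, k: int, rng: np.random.Generator,
         max_iter: int = 100) -> np.ndarray:
    """Partition around medoids on cosine distance; returns medoid indices.

    Voronoi-iteration PAM: assign points to nearest medoid, then move each
    medoid to the member minimizing total within-cluster distance.
    """
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    Xn = X / np.maximum(norms, 1e-12)
    D = 1.0 - np.clip(Xn @ Xn.T, -1.0, 1.0)
    n = len(X)
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.nonzero(assign == c)[0]
            if len(members) == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return medoids


@dataclass
class RankResult:
    """Extraction result for one candidate number of signatures k."""

    k: int
    profiles: np.ndarray           # k x channels, rows sum to 1
    stability: float               # mean silhouette of replicate clustering
    reconstruction_error: float    # mean KL divergence across replicates
    n_replicates: int


@dataclass
class SignatureSet:
    """Selected signatures with exposures and reference matches."""

    k: int
    channels: list[str]
    profiles: pd.DataFrame                 # signatures x channels
    exposures: pd.DataFrame | None = None  # signatures x samples
    sample_cosines: pd.Series | None = None
    reference_matches: pd.DataFrame | None = None
    rank_results: dict[int, RankResult] = field(default_factory=dict)


def extract_signatures(
    matrix: pd.DataFrame,
    k_range: range | list[int] = range(1, 16),
    n_replicates: int = 100,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> dict[int, RankResult]:
    """Extract candidate signatures for each rank in ``k_range``.

    For each k: Poisson-bootstrap the counts, run KL-NMF per replicate,
    pool the replicate signatures, PAM-cluster them into k groups on cosine
    distance, and report the medoid profiles plus the mean silhouette
    (stability) and mean reconstruction KL divergence.  Deterministic for a
    fixed seed.
    """
    V = matrix.to_numpy(dtype=float)
    n_samples = V.shape[1]
    results: dict[int, RankResult] = {}
    for k in k_range:
        if k > n_samples:
            logger.warning("skipping k=%d > %d samples", k, n_samples)
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(k,))
        )
        all_sigs = []
        errors = []
        for rep in range(n_replicates):
            Vb = rng.poisson(V).astype(float)
            if Vb.sum() == 0:
                continue
            W, H, _ = _fit_nmf(Vb, k, seed=int(rng.integers(2**31)),
                               tol=tol, max_iter=max_iter)
            # evaluate the replicate factorization against the observed matrix
            errors.append(_kl_divergence(V, W, H))
            colsum = W.sum(axis=0)
            colsum[colsum == 0] = 1.0
            all_sigs.append((W / colsum).T)  # k x channels, normalized
        sigs = np.vstack(all_sigs)
        if k == 1:
            medoid_idx = _pam(sigs, 1, rng)
            medoid = sigs[medoid_idx[0]]
            norms = np.linalg.norm(sigs, axis=1) * np.linalg.norm(medoid)
            sims = sigs @ medoid / np.maximum(norms, 1e-12)
            stability = float(sims.mean())
            profiles = medoid[None, :]
        else:
            medoid_idx = _pam(sigs, k, rng)
            Xn = sigs / np.maximum(np.linalg.norm(sigs, axis=1, keepdims=True), 1e-12)
            D = 1.0 - np.clip(Xn @ Xn.T, -1.0, 1.0)
            labels = np.argmin(D[:, medoid_idx], axis=1)
            if len(set(labels)) < 2:
                stability = 0.0
            else:
                stability = float(silhouette_score(D, labels, metric="precomputed"))
            profiles = sigs[medoid_idx]
        profiles = profiles / profiles.sum(axis=1, keepdims=True)
        results[k] = RankResult(
            k=k, profiles=profiles, stability=stability,
            reconstruction_error=float(np.mean(errors)),
            n_replicates=len(errors),
        )
    return results


def select_k(
    results: dict[int, RankResult],
    min_stability: float = 0.80,
    min_improvement: float = 0.01,
) -> int:
    """Choose the number of signatures from rank-candidate results.

    The largest k whose stability is >= ``min_stability`` and whose mean
    reconstruction error improves on k - 1 by more than ``min_improvement``
    (relative).  k = 1 needs only the stability condition.  Falls back to
    k = 1 with a warning when nothing qualifies.
    """
    if not results:
        raise ValueError("no rank results")
    ks = sorted(results)
    best = None
    for k in ks:
        r = results[k]
        if r.stability < min_stability:
            continue
        if k == ks[0]:
            best = k
            continue
        prev = results.get(k - 1)
        if prev is None or prev.reconstruction_error <= 0:
            continue
        rel = (prev.reconstruction_error - r.reconstruction_error) / prev.reconstruction_error
        if rel > min_improvement:
            best = k
    if best is None:
        logger.warning("no rank met the stability/improvement rule; using k=1")
        best = ks[0]
    return best


def assign_exposures(
    matrix: pd.DataFrame, profiles: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Non-negative least-squares exposures plus reconstruction cosines.

    ``profiles`` is signatures x channels.  Returns (exposures
    [signatures x samples], per-sample cosine).  Zero-count samples get zero
    exposures and NaN cosine.
    """
    P = profiles.to_numpy(dtype=float).T  # channels x signatures
    expo = np.zeros((profiles.shape[0], matrix.shape[1]))
    cosines = np.full(matrix.shape[1], np.nan)
    V = matrix.to_numpy(dtype=float)
    for j in range(matrix.shape[1]):
        v = V[:, j]
        if v.sum() == 0:
            continue
        x, _ = nnls(P, v)
        expo[:, j] = x
        cosines[j] = cosine(v, P @ x)
    exposures = pd.DataFrame(expo, index=profiles.index, columns=matrix.columns)
    return exposures, pd.Series(cosines, index=matrix.columns, name="cosine")


def match_reference(
    profiles: pd.DataFrame,
    catalog: pd.DataFrame,
    threshold: float = 0.80,
) -> pd.DataFrame:
    """Match extracted profiles to a reference catalog by cosine similarity.

    For each profile, the best single reference and the best two-reference
    non-negative combination are evaluated; the match is whichever scores
    higher, and it counts as matched only at cosine >= ``threshold``.  The
    best cosine is always reported.
    """
    refs = catalog.to_numpy(dtype=float)
    ref_names = list(catalog.index)
    rows = []
    for name, prof in profiles.iterrows():
        v = prof.to_numpy(dtype=float)
        best_single = max(range(len(refs)), key=lambda i: cosine(v, refs[i]))
        best_cos = cosine(v, refs[best_single])
        best_ref: str = ref_names[best_single]
        for i in range(len(refs)):
            for j in range(i + 1, len(refs)):
                A = np.stack([refs[i], refs[j]], axis=1)
                x, _ = nnls(A, v)
                if x.sum() == 0:
                    continue
                c = cosine(v, A @ x)
                if c > best_cos + 1e-9:
                    best_cos = c
                    best_ref = f"{ref_names[i]}+{ref_names[j]}"
        rows.append({
            "signature": name, "reference": best_ref,
            "cosine": best_cos, "matched": best_cos >= threshold,
        })
    return pd.DataFrame(rows)


def prevalence(
    exposures: pd.DataFrame,
    sample_cosines: pd.Series,
    metadata: pd.DataFrame,
    min_cosine: float = 0.80,
    min_svs_assigned: float = 1.0,
) -> pd.DataFrame:
    """Percentage of samples positive for each signature, per cancer type.

    A sample is positive when at least one SV is assigned to the signature
    AND its reconstruction cosine is >= ``min_cosine``; low-cosine samples
    count as negative for every signature but stay in the denominator.
    """
    type_of = metadata.set_index("sample_id")["cancer_type"]
    ok = sample_cosines >= min_cosine
    pos = exposures.ge(min_svs_assigned) & ok
    rows = []
    for ctype in sorted(type_of.loc[type_of.index.isin(exposures.columns)].unique()):
        cols = [s for s in exposures.columns if type_of.get(s) == ctype]
        denom = len(cols)
        for sig in exposures.index:
            rows.append({
                "cancer_type": ctype, "signature": sig,
                "percent_positive": 100.0 * pos.loc[sig, cols].sum() / denom,
                "n_samples": denom,
            })
    return pd.DataFrame(rows)
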