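"""Cancer-cell-fraction computation and clonal-architecture inference.

The cancer cell fraction (CCF) of a mutation is the fraction of cancer
cells that carry it, obtained from the variant allele fraction (VAF) with a
purity and copy-number correction::

    CCF = VAF * (rho * CNt + (1 - rho) * CNn) / (rho * m)

where ``rho`` is tumour purity, ``CNt``/``CNn`` the tumour and normal local
total copy numbers and ``m`` the mutation multiplicity (mutated copies per
cancer cell). Values are clipped to [0, 1.5] to tolerate copy-number
misestimates.

Multi-region clone inference clusters mutations by their per-region read
counts with an expectation-maximisation fit of a binomial mixture: cluster
``k`` has a per-region CCF ``phi_kr``, and a mutation's alt count in region
``r`` is Binomial(depth, phi_kr * c_r) where ``c_r`` converts CCF to
expected VAF (``c = rho * m / (rho * CNt + (1 - rho) * CNn)``). The number
of clusters is chosen by BIC. The per-cluster per-region CCF is reported as
the clone's "clonality"; a clone is dominant in a region when its clonality
exceeds 0.5. Because clones are nested along the tumour phylogeny, several
clones may be dominant at once and clonalities need not sum to one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import mannwhitneyu

from .variants import CnvSegment, MutationRecord, RegionSample

logger = logging.getLogger(__name__)

_EPS = 1e-6
CCF_MAX = 1.5


def compute_ccf(
    vaf: float,
    purity: float,
    cn_tumour: int = 2,
    cn_normal: int = 2,
    multiplicity: int = 1,
) -> float:
    """Purity- and copy-number-corrected cancer cell fraction.

    Clipped to [0, 1.5]; clipping events are logged.
    """
    if purity <= 0:
        raise ValueError("purity must be > 0")
    if not 0 <= vaf <= 1:
        raise ValueError(f"vaf must be in [0, 1]: {vaf}")
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    ccf = vaf * (purity * cn_tumour + (1 - purity) * cn_normal) / (purity * multiplicity)
    if ccf > CCF_MAX:
        logger.info("CCF %.3f clipped to %.1f (vaf=%.3f purity=%.2f)", ccf, CCF_MAX, vaf, purity)
        ccf = CCF_MAX
    return max(ccf, 0.0)


def estimate_multiplicity(
    vaf: float, purity: float, cn_tumour: int = 2, cn_normal: int = 2
) -> int:
    """Most-likely integer mutation multiplicity given VAF, purity and CN.

    Rounds the implied mutated-copy number and clips to [1, max(CNt, 1)].
    """
    if purity <= 0:
        raise ValueError("purity must be > 0")
    raw = vaf * (purity * cn_tumour + (1 - purity) * cn_normal) / purity
    return int(np.clip(round(raw), 1, max(cn_tumour, 1)))


def call_clonal_status(ccf: float, clonal_threshold: float = 0.9) -> str:
    """'clonal' when CCF >= threshold, else 'subclonal'."""
    if ccf < 0:
        raise ValueError("ccf must be >= 0")
    return "clonal" if ccf >= clonal_threshold else "subclonal"


@dataclass
class CcfEstimate:
    mutation_key: str
    region_id: str
    vaf: float
    purity: float
    cn_tumour: int
    cn_normal: int
    multiplicity: int
    ccf: float
    status: str  # clonal / subclonal / absent


def vaf_factor(
    purity: float, cn_tumour: int = 2, cn_normal: int = 2, multiplicity: int = 1
) -> float:
    """Factor c with expected VAF = CCF * c."""
    return purity * multiplicity / (purity * cn_tumour + (1 - purity) * cn_normal)


def _segment_cn(
    segments: Sequence[CnvSegment] | None, region_id: str, chrom: str, pos: int
) -> int:
    """Tumour total copy number at a locus from called segments (default 2)."""
    if not segments:
        return 2
    for seg in segments:
        if seg.region_id == region_id and seg.chrom == chrom and seg.start <= pos <= seg.end:
            cn = round(2 * 2 ** seg.log2_ratio)
            return max(int(cn), 0)
    return 2


def ccf_estimates(
    records: Sequence[MutationRecord],
    regions: Sequence[RegionSample],
    segments: Sequence[CnvSegment] | None = None,
    min_alt_reads: int = 3,
    min_vaf: float = 0.05,
    clonal_threshold: float = 0.9,
) -> list[CcfEstimate]:
    """Per-mutation per-region CCF estimates with clonal/subclonal status.

    A mutation failing the detection rule in a region is reported with
    status ``absent``.
    """
    purity_by_region = {r.region_id: r.purity for r in regions}
    out: list[CcfEstimate] = []
    for rec in records:
        for region in regions:
            rid = region.region_id
            a, t = rec.per_region.get(rid, (0, 0))
            vaf = a / t if t else 0.0
            cnt = _segment_cn(segments, rid, rec.chrom, rec.pos)
            rho = purity_by_region[rid]
            m = estimate_multiplicity(vaf, rho, cnt) if vaf > 0 else 1
            ccf = compute_ccf(vaf, rho, cnt, 2, m)
            detected = a >= min_alt_reads and t > 0 and vaf >= min_vaf
            status = call_clonal_status(ccf, clonal_threshold) if detected else "absent"
            out.append(
                CcfEstimate(
                    mutation_key=rec.key,
                    region_id=rid,
                    vaf=vaf,
                    purity=rho,
                    cn_tumour=cnt,
                    cn_normal=2,
                    multiplicity=m,
                    ccf=ccf,
                    status=status,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Binomial-mixture EM clone inference
# ---------------------------------------------------------------------------


@dataclass
class CloneModel:
    """Inferred clonal architecture of one tumour."""

    clones: list[str]
    clonality: pd.DataFrame  # clones x regions, per-region clone CCF
    assignment: dict[str, str]  # mutation key -> clone id
    bic: float
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def regions(self) -> list[str]:
        return list(self.clonality.columns)

    def mutation_sets(self) -> dict[str, set[str]]:
        sets: dict[str, set[str]] = {c: set() for c in self.clones}
        for key, clone in self.assignment.items():
            sets[clone].add(key)
        return sets


def _loglik_matrix(A, D, C, phi, log_pi):
    """Per-mutation per-cluster log likelihood (N x K), binomial kernel."""
    V = np.clip(phi[None, :, :] * C[:, None, :], _EPS, 1 - _EPS)  # N x K x R
    ll = A[:, None, :] * np.log(V) + (D - A)[:, None, :] * np.log1p(-V)
    return ll.sum(axis=2) + log_pi[None, :]


def _mstep_phi(A, D, C, W, phi, constant_c, c_cols):
    K = W.shape[1]
    if constant_c:
        num = W.T @ A  # K x R
        den = (W.T @ D) * c_cols[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            phi_new = np.where(den > 0, num / den, 0.0)
        return np.clip(phi_new, _EPS, 1.0)
    # general case: concave 1-d problems solved by bisection on the score,
    # vectorised over all (cluster, region) cells at once
    R = phi.shape[1]
    BC = (D - A) * C  # N x R, constant within the step
    WA = W.T @ A  # K x R
    Ck = C[:, None, :]  # N x 1 x R
    lo = np.full((K, R), _EPS)
    hi = np.ones((K, R))
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        denom = 1.0 - mid[None, :, :] * Ck
        np.maximum(denom, _EPS, out=denom)
        term2 = np.einsum("ik,ikr->kr", W, BC[:, None, :] / denom)
        pos = WA / mid - term2 > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    return np.clip(0.5 * (lo + hi), _EPS, 1.0)


def _run_em(A, D, C, K, rng, max_iter, tol, constant_c, c_cols):
    N, R = A.shape
    # k-means++-style seeding on naive CCF point estimates
    with np.errstate(invalid="ignore", divide="ignore"):
        ccf_hat = np.where(D > 0, A / np.maximum(D * C, _EPS), 0.0)
    ccf_hat = np.clip(ccf_hat, 0.0, CCF_MAX)
    centers = [ccf_hat[rng.integers(N)]]
    for _ in range(1, K):
        d2 = np.min(
            [((ccf_hat - c) ** 2).sum(axis=1) for c in centers], axis=0
        )
        total = d2.sum()
        if total <= 0:
            centers.append(ccf_hat[rng.integers(N)])
        else:
            centers.append(ccf_hat[rng.choice(N, p=d2 / total)])
    centers = np.array(centers)
    assign = np.argmin(
        ((ccf_hat[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    W = np.full((N, K), 0.05 / max(K - 1, 1))
    W[np.arange(N), assign] = 0.95 if K > 1 else 1.0
    phi = np.clip(centers, _EPS, 1.0)
    pi = W.mean(axis=0)

    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        phi = _mstep_phi(A, D, C, W, phi, constant_c, c_cols)
        pi = np.clip(W.mean(axis=0), 1e-12, None)
        pi = pi / pi.sum()
        ll_mat = _loglik_matrix(A, D, C, phi, np.log(pi))
        ll_tot = float(logsumexp(ll_mat, axis=1).sum())
        trace.append(ll_tot)
        W = np.exp(ll_mat - logsumexp(ll_mat, axis=1, keepdims=True))
        if ll_tot - prev < tol and np.isfinite(prev):
            break
        prev = ll_tot
    return phi, pi, W, trace


def infer_clones(
    alt: np.ndarray,
    total: np.ndarray,
    c_factor: np.ndarray,
    region_ids: Sequence[str] | None = None,
    mutation_keys: Sequence[str] | None = None,
    max_clones: int = 8,
    n_restarts: int = 10,
    max_iter: int = 200,
    seed: int = 0,
) -> CloneModel:
    """Cluster mutations into clones from per-region read counts.

    Parameters
    ----------
    alt, total : (N, R) integer arrays
        Per-mutation per-region alt and total read counts.
    c_factor : (R,) or (N, R) array
        CCF-to-VAF conversion factor per region (see :func:`vaf_factor`).
    max_clones : int
        Candidate cluster counts are 1..max_clones; BIC selects among them.

    The EM likelihood is non-decreasing over iterations (recorded in
    ``loglik_trace`` of the winning fit); fits are deterministic for a
    given seed.
    """
    A = np.asarray(alt, dtype=float)
    D = np.asarray(total, dtype=float)
    if A.ndim != 2 or A.shape != D.shape:
        raise ValueError("alt and total must be matching 2-d arrays")
    N, R = A.shape
    C = np.asarray(c_factor, dtype=float)
    if C.ndim == 1:
        C = np.broadcast_to(C, (N, R)).copy()
    if C.shape != (N, R):
        raise ValueError("c_factor must have shape (R,) or (N, R)")
    region_ids = list(region_ids) if region_ids else [f"R{j + 1}" for j in range(R)]
    mutation_keys = (
        list(mutation_keys) if mutation_keys else [f"M{i + 1}" for i in range(N)]
    )

    constant_c = bool(np.all(np.ptp(C, axis=0) < 1e-12))
    c_cols = C[0] if constant_c else None

    if N < 2:
        warnings.warn("fewer than 2 mutations; returning a single-clone model", stacklevel=2)
        max_clones = 1

    rng = np.random.default_rng(seed)
    tol = 1e-4 * max(N, 1)
    best = None
    for K in range(1, max_clones + 1):
        if K > N:
            break
        best_k = None
        for _ in range(n_restarts if K > 1 else 1):
            phi, pi, W, trace = _run_em(A, D, C, K, rng, max_iter, tol, constant_c, c_cols)
            if best_k is None or trace[-1] > best_k[3][-1]:
                best_k = (phi, pi, W, trace)
        phi, pi, W, trace = best_k
        n_params = K * R + (K - 1)
        bic = -2.0 * trace[-1] + n_params * np.log(N * R)
        if best is None or bic < best[0]:
            best = (bic, K, phi, pi, W, trace)

    bic, K, phi, pi, W, trace = best
    # order clones by total clonality, descending (clone 1 ~ trunk)
    order = np.argsort(-phi.sum(axis=1))
    phi = phi[order]
    W = W[:, order]
    clone_ids = [f"C{j + 1}" for j in range(K)]
    hard = np.argmax(W, axis=1)
    assignment = {mutation_keys[i]: clone_ids[hard[i]] for i in range(N)}
    clonality = pd.DataFrame(phi, index=clone_ids, columns=region_ids)
    return CloneModel(
        clones=clone_ids,
        clonality=clonality,
        assignment=assignment,
        bic=float(bic),
        loglik_trace=[float(x) for x in trace],
    )


def infer_clones_for_patient(
    records: Sequence[MutationRecord],
    regions: Sequence[RegionSample],
    segments: Sequence[CnvSegment] | None = None,
    max_clones: int = 8,
    n_restarts: int = 10,
    seed: int = 0,
) -> CloneModel:
    """Convenience wrapper: build count matrices from records and infer clones."""
    region_ids = [r.region_id for r in regions]
    N = len(records)
    A = np.zeros((N, len(region_ids)))
    D = np.zeros((N, len(region_ids)))
    C = np.zeros((N, len(region_ids)))
    for i, rec in enumerate(records):
        for j, region in enumerate(regions):
            a, t = rec.per_region.get(region.region_id, (0, 0))
            A[i, j], D[i, j] = a, t
            cnt = _segment_cn(segments, region.region_id, rec.chrom, rec.pos)
            C[i, j] = vaf_factor(region.purity, cnt, 2, 1)
    return infer_clones(
        A, D, C,
        region_ids=region_ids,
        mutation_keys=[r.key for r in records],
        max_clones=max_clones,
        n_restarts=n_restarts,
        seed=seed,
    )


def dominant_subclones(model: CloneModel, region_id: str) -> set[str]:
    """Clones with clonality strictly above 0.5 in the given region."""
    if region_id not in model.clonality.columns:
        raise KeyError(f"unknown region: {region_id!r}")
    col = model.clonality[region_id]
    return set(col.index[col > 0.5])


# ---------------------------------------------------------------------------
# Dual-tumour clonal relationship
# ---------------------------------------------------------------------------


def classify_clonal_relationship(
    model_a: CloneModel,
    model_b: CloneModel,
    min_shared_mutations: int = 5,
    min_jaccard: float = 0.5,
) -> tuple[int, str]:
    """Count clones shared between two tumours of one patient.

    Clones are matched by mutation identity: a pair matches when it shares
    at least ``min_shared_mutations`` identical variants or the Jaccard
    index of the two mutation sets reaches ``min_jaccard``. Matching is
    one-to-one, greedy by shared-mutation count. Labels: 0 shared ->
    "not clonal"; 1 -> "one subclone in common"; >= 2 -> "clonally related".
    """
    if model_a is None or model_b is None:
        raise ValueError("both tumour clone models are required")
    sets_a = model_a.mutation_sets()
    sets_b = model_b.mutation_sets()
    pairs = []
    for ca, sa in sets_a.items():
        for cb, sb in sets_b.items():
            inter = len(sa & sb)
            union = len(sa | sb)
            jac = inter / union if union else 0.0
            if inter >= min_shared_mutations or (inter > 0 and jac >= min_jaccard):
                pairs.append((inter, jac, ca, cb))
    pairs.sort(key=lambda p: (-p[0], -p[1], p[2], p[3]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    n_shared = 0
    for inter, jac, ca, cb in pairs:
        if ca in used_a or cb in used_b:
            continue
        used_a.add(ca)
        used_b.add(cb)
        n_shared += 1
    if n_shared == 0:
        label = "not clonal"
    elif n_shared == 1:
        label = "one subclone in common"
    else:
        label = "clonally related"
    return n_shared, label


# ---------------------------------------------------------------------------
# Differential copy number between paired tumours
# ---------------------------------------------------------------------------


def differential_cnv(
    segments_a: Sequence[CnvSegment],
    segments_b: Sequence[CnvSegment],
    bins: Sequence[tuple[str, int, int]] | None = None,
    p_thresh: float = 0.01,
    q_thresh: float = 0.15,
    fallback_delta: float = 2.0,
) -> pd.DataFrame:
    """Screen genomic bins for differential copy number between two tumours.

    Per bin, the per-region mean log2 ratios of tumour A are compared with
    those of tumour B by an exact two-sided Wilcoxon rank-sum test;
    Benjamini-Hochberg q-values are computed across bins and the returned
    table is filtered at ``p < p_thresh`` and ``q < q_thresh``. When either
    tumour contributes a single region the rank test is infeasible and a
    |mean difference| >= ``fallback_delta`` rule is applied instead (with a
    warning).
    """
    from statsmodels.stats.multitest import multipletests

    if not segments_a or not segments_b:
        raise ValueError("both tumours need at least one region with segments")
    if bins is None:
        bins = sorted(
            {(s.chrom, s.start, s.end) for s in list(segments_a) + list(segments_b)},
            key=lambda b: (b[0], b[1]),
        )

    def region_values(segments, chrom, start, end):
        vals: dict[str, list[float]] = {}
        for s in segments:
            if s.chrom == chrom and s.start <= end and s.end >= start:
                vals.setdefault(s.region_id, []).append(s.log2_ratio)
        return np.array([float(np.mean(v)) for v in vals.values()])

    rows = []
    single_region = False
    for chrom, start, end in bins:
        xa = region_values(segments_a, chrom, start, end)
        xb = region_values(segments_b, chrom, start, end)
        if len(xa) == 0 or len(xb) == 0:
            continue
        if len(xa) < 2 or len(xb) < 2:
            single_region = True
            delta = float(xa.mean() - xb.mean())
            p = 0.0 if abs(delta) >= fallback_delta else 1.0
        else:
            if np.ptp(np.concatenate([xa, xb])) == 0:
                p = 1.0
            else:
                p = float(mannwhitneyu(xa, xb, alternative="two-sided", method="exact").pvalue)
        rows.append({"chrom": chrom, "start": start, "end": end, "p": p,
                     "delta_log2": float(xa.mean() - xb.mean())})
    if single_region:
        warnings.warn(
            "a tumour has a single region in some bins; used the "
            f"|delta log2| >= {fallback_delta} fallback rule there",
            stacklevel=2,
        )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "p", "delta_log2"])
    if df.empty:
        df["q"] = []
        return df
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    hits = df[(df["p"] < p_thresh) & (df["q"] < q_thresh)].reset_index(drop=True)
    return hits
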