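"""Synthetic multi-region tumour cohorts with known ground truth.

Each simulated patient carries a random clone tree: the root clone's
mutations are fully clonal in every region (the trunk) and every non-root
clone occupies a random non-empty subset of its parent's regions, which
guarantees the nested trunk/branch semantics of multi-region sampling.
Per-region clone proportions are Dirichlet draws over the clones occupying
the region; a clone's CCF in a region is its subtree proportion sum.

Read counts follow the standard generative model: sequencing depth is
Poisson around ``depth_mean`` and alt reads are Binomial with expected VAF
``purity * CCF * m / (purity * CNt + (1 - purity) * 2)`` for multiplicity
``m`` and local tumour copy number ``CNt``. Copy-number events are
whole-chromosome gains/losses at configurable rates; trinucleotide channels
are drawn i.i.d. from the patient's signature mixture over a bundled
synthetic catalogue; binary clinical covariates are drawn conditionally on
the patient's true signature-16 status.

Dual-tumour patients get two independently simulated tumours (oesophagus
and hypopharynx) sharing either zero clones or exactly one designated
clone, mirroring the two clonal-relationship classes seen in synchronous
dual primaries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._channels import channel_to_snv
from .signatures import SignatureCatalog, default_catalog
from .variants import (
    CnvSegment,
    MutationRecord,
    RegionSample,
    write_mutation_table,
    write_region_table,
    write_seg,
)

_CHROM_LENGTH = 200_000_000
_MAX_TREE_RETRIES = 20

#: Default functional-class frequencies for simulated exonic mutations.
DEFAULT_CLASS_PROBS = {
    "nonsynonymous": 0.55,
    "synonymous": 0.20,
    "noncoding": 0.10,
    "stopgain": 0.05,
    "frameshift_indel": 0.05,
    "nonframeshift_indel": 0.04,
    "stoploss": 0.01,
}

#: Conditional covariate probabilities P(covariate | sig16 present/absent),
#: taken from the cohort's printed 2x2 margins (13 signature-positive of 18).
DEFAULT_COVARIATE_MODEL = {
    "drinking": (12 / 13, 1 / 5),
    "smoking": (10 / 13, 1 / 5),
    "male": (1.0, 2 / 5),
    "dual_primary": (8 / 13, 0.0),
    "relapse": (7 / 13, 0.0),
    "dead": (6 / 13, 0.0),
}


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the emulated study: 18 patients, 4-6 regions per
    tumour, 1-6 clones, ~80x mean depth, purity 0.3-0.9, and a
    signature-16 prevalence of 13/18 driving the clinical covariates.
    """

    n_patients: int = 18
    regions_per_tumour: tuple[int, int] = (4, 6)
    n_clones: tuple[int, int] = (1, 6)
    mutations_per_clone: tuple[int, int] = (10, 30)
    depth_mean: float = 80.0
    purity_range: tuple[float, float] = (0.3, 0.9)
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    p_sig16: float = 13 / 18
    sig16_weight_range: tuple[float, float] = (0.15, 0.40)
    covariate_model: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MODEL)
    )
    arm_gain_rate: float = 0.05
    arm_loss_rate: float = 0.05
    gain_cn_range: tuple[int, int] = (5, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (
            self.regions_per_tumour,
            self.n_clones,
            self.mutations_per_clone,
        ):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be non-empty with positive bounds")
        if not 0 < self.purity_range[0] <= self.purity_range[1] <= 1:
            raise ValueError("purity_range must lie in (0, 1]")
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        for name, (p1, p0) in self.covariate_model.items():
            if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
                raise ValueError(f"covariate_model[{name}] out of [0, 1]")


@dataclass
class CloneTreeTruth:
    """Ground-truth clonal architecture of one simulated tumour."""

    clone_ids: list[str]
    parent: dict[str, str | None]
    mutations_per_clone: dict[str, list[str]]
    occupancy: dict[str, list[str]]  # clone -> regions where subtree present
    region_fractions: dict[str, dict[str, float]]  # disjoint clone proportions
    ccf: dict[str, dict[str, float]]  # clone -> region -> subtree CCF

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def clone_of(self) -> dict[str, str]:
        return {
            key: clone
            for clone, keys in self.mutations_per_clone.items()
            for key in keys
        }

    def expected_label(self, key: str, n_regions: int) -> str:
        """Truth trunk/branch label implied by the owning clone's occupancy."""
        clone = self.clone_of()[key]
        occ = len(self.occupancy[clone])
        if occ == n_regions:
            return "trunk"
        return "private_branch" if occ == 1 else "shared_branch"


@dataclass
class PatientSim:
    patient_id: str
    tumour_site: str
    truth: CloneTreeTruth
    records: list[MutationRecord]
    regions: list[RegionSample]
    segments: list[CnvSegment]
    expected_vaf: dict[str, dict[str, float]] = field(default_factory=dict)

    def detectable_regions(
        self, key: str, depth: float, min_alt_reads: int = 3, min_vaf: float = 0.05
    ) -> list[str]:
        """Regions where the mutation's expected VAF passes the detection rule.

        Uses the noise-free expected VAF and mean depth, i.e. the truth
        occupancy composed with the detection rule; read-level noise can
        still flip calls near the thresholds.
        """
        out = []
        for rid, vaf in self.expected_vaf.get(key, {}).items():
            if vaf >= min_vaf and depth * vaf >= min_alt_reads:
                out.append(rid)
        return out

    def detectable_label(
        self, key: str, depth: float, min_alt_reads: int = 3, min_vaf: float = 0.05
    ) -> str | None:
        """Expected trunk/branch label under the detection rule (None if invisible)."""
        det = self.detectable_regions(key, depth, min_alt_reads, min_vaf)
        if not det:
            return None
        if len(det) == len(self.regions):
            return "trunk"
        return "private_branch" if len(det) == 1 else "shared_branch"


@dataclass
class DualTumourSim:
    patient_id: str
    tumour_a: PatientSim
    tumour_b: PatientSim
    shared_clones: int
    shared_mutation_keys: set[str]


@dataclass
class CohortBundle:
    config: SimulationConfig
    seed: int
    patients: list  # PatientSim | DualTumourSim
    covariates: pd.DataFrame  # one row per patient, binary columns + sig16
    signature_weights: dict[str, dict[str, float]]


# ---------------------------------------------------------------------------
# Core tree and read-count machinery
# ---------------------------------------------------------------------------


def _sample_tree(rng, n_clones: int, region_ids: list[str]):
    """Uniform recursive attachment; nested spatially segregated occupancy.

    Each non-root clone occupies a random non-empty subset of its parent's
    regions, drawn preferentially from regions not yet claimed by its
    siblings: subclones segregate spatially, as multi-region sampling of
    solid tumours typically shows. Overlap arises only when a parent's
    regions are exhausted.
    """
    parent: dict[str, str | None] = {"C1": None}
    occupancy: dict[str, list[str]] = {"C1": list(region_ids)}
    child_used: dict[str, set[str]] = {"C1": set()}
    for j in range(2, n_clones + 1):
        cid = f"C{j}"
        pid = f"C{rng.integers(1, j)}"
        parent[cid] = pid
        available = [r for r in occupancy[pid] if r not in child_used[pid]]
        if available:
            keep = [r for r in available if rng.random() < 0.6]
            if not keep:
                keep = [available[rng.integers(len(available))]]
        else:
            keep = [occupancy[pid][rng.integers(len(occupancy[pid]))]]
        occupancy[cid] = keep
        child_used[pid].update(keep)
        child_used[cid] = set()
    return parent, occupancy


def _sample_fractions(rng, clone_ids, parent, occupancy, region_ids):
    """Dirichlet clone proportions per region; returns (fractions, ccf)."""
    fractions = {c: {} for c in clone_ids}
    for r in region_ids:
        members = [c for c in clone_ids if r in occupancy[c]]
        weights = rng.dirichlet(np.ones(len(members)))
        for c, w in zip(members, weights):
            fractions[c][r] = float(w)
    children: dict[str, list[str]] = {c: [] for c in clone_ids}
    for c, p in parent.items():
        if p is not None:
            children[p].append(c)

    def subtree_sum(c: str, r: str) -> float:
        total = fractions[c].get(r, 0.0)
        for child in children[c]:
            total += subtree_sum(child, r)
        return total

    ccf = {
        c: {r: subtree_sum(c, r) for r in region_ids if r in occupancy[c]}
        for c in clone_ids
    }
    return fractions, ccf


def _check_tree(truth: CloneTreeTruth, region_ids) -> bool:
    for r in region_ids:
        total = sum(truth.region_fractions[c].get(r, 0.0) for c in truth.clone_ids)
        if total > 1 + 1e-9:
            return False
        for c in truth.clone_ids:
            p = truth.parent[c]
            if p is not None:
                if truth.ccf[c].get(r, 0.0) > truth.ccf[p].get(r, 0.0) + 1e-9:
                    return False
    return True


def _draw_mutation_site(rng, used_keys: set[str], channel: int | None, is_indel: bool):
    """Random locus plus ref/alt consistent with the channel (or an indel)."""
    for _ in range(100):
        chrom = str(rng.integers(1, 23))
        pos = int(rng.integers(10_000, _CHROM_LENGTH))
        if is_indel:
            if rng.random() < 0.5:
                ref, alt = "A", "AT"  # insertion
            else:
                ref, alt = "AT", "A"  # deletion
        else:
            ref, alt, _ = channel_to_snv(channel)
        key = f"{chrom}:{pos}:{ref}>{alt}"
        if key not in used_keys:
            used_keys.add(key)
            return chrom, pos, ref, alt
    raise RuntimeError("could not draw a unique mutation site")


def _simulate_tumour(
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str,
    tumour_site: str,
    region_prefix: str,
    signature_weights: dict[str, float],
    catalog: SignatureCatalog,
    used_keys: set[str],
) -> PatientSim:
    n_regions = int(rng.integers(*config.regions_per_tumour, endpoint=True))
    region_ids = [f"{patient_id}_{region_prefix}R{i + 1}" for i in range(n_regions)]
    purities = rng.uniform(*config.purity_range, size=n_regions)
    regions = [
        RegionSample(
            patient_id=patient_id,
            tumour_site=tumour_site,
            region_id=rid,
            purity=float(p),
            carcinoma_content=float(min(1.0, p + rng.uniform(0.0, 0.1))),
        )
        for rid, p in zip(region_ids, purities)
    ]

    n_clones = int(rng.integers(*config.n_clones, endpoint=True))
    truth = None
    for _ in range(_MAX_TREE_RETRIES):
        parent, occupancy = _sample_tree(rng, n_clones, region_ids)
        clone_ids = sorted(parent, key=lambda c: int(c[1:]))
        fractions, ccf = _sample_fractions(rng, clone_ids, parent, occupancy, region_ids)
        candidate = CloneTreeTruth(
            clone_ids=clone_ids,
            parent=parent,
            mutations_per_clone={c: [] for c in clone_ids},
            occupancy=occupancy,
            region_fractions=fractions,
            ccf=ccf,
        )
        if _check_tree(candidate, region_ids):
            truth = candidate
            break
    if truth is None:
        raise RuntimeError("could not sample a consistent clone tree")

    # whole-chromosome copy-number events (clonal across regions)
    chrom_cn = {str(c): 2 for c in range(1, 23)}
    for chrom in chrom_cn:
        u = rng.random()
        if u < config.arm_gain_rate:
            chrom_cn[chrom] = int(rng.integers(*config.gain_cn_range, endpoint=True))
        elif u < config.arm_gain_rate + config.arm_loss_rate:
            chrom_cn[chrom] = int(rng.integers(0, 2))
    segments = [
        CnvSegment(
            region_id=rid,
            chrom=chrom,
            start=1,
            end=_CHROM_LENGTH,
            log2_ratio=float(
                np.log2(max(cn, 0.1) / 2.0) + rng.normal(0.0, 0.05)
            ),
        )
        for rid in region_ids
        for chrom, cn in chrom_cn.items()
    ]

    mixture = np.array([signature_weights.get(n, 0.0) for n in catalog.names])
    mixture = mixture / mixture.sum()
    channel_probs = catalog.matrix @ mixture
    class_names = list(config.class_probs)
    class_p = np.array([config.class_probs[c] for c in class_names])

    records: list[MutationRecord] = []
    expected_vaf: dict[str, dict[str, float]] = {}
    for clone in truth.clone_ids:
        n_mut = int(rng.integers(*config.mutations_per_clone, endpoint=True))
        for i in range(max(n_mut, 1)):
            fclass = class_names[rng.choice(len(class_names), p=class_p)]
            is_indel = fclass in ("frameshift_indel", "nonframeshift_indel")
            channel = None if is_indel else int(
                rng.choice(96, p=channel_probs)
            )
            # mutations on homozygously deleted chromosomes are unobservable;
            # place them on chromosomes retaining at least one copy
            while True:
                chrom, pos, ref, alt = _draw_mutation_site(
                    rng, used_keys, channel, is_indel
                )
                if chrom_cn[chrom] >= 1:
                    break
            cnt = chrom_cn[chrom]
            # multiplicity uniform on {1..CNt} on gained chromosomes, else 1
            mult = int(rng.integers(1, cnt, endpoint=True)) if cnt > 2 else 1
            per_region: dict[str, tuple[int, int]] = {}
            vaf_by_region: dict[str, float] = {}
            for region in regions:
                rid = region.region_id
                ccf_val = truth.ccf[clone].get(rid, 0.0)
                rho = region.purity
                vaf = rho * ccf_val * mult / (rho * cnt + (1 - rho) * 2)
                vaf_by_region[rid] = min(vaf, 1.0)
                depth = int(rng.poisson(config.depth_mean))
                alt_reads = int(rng.binomial(depth, min(vaf, 1.0))) if depth else 0
                per_region[rid] = (alt_reads, depth)
            rec = MutationRecord(
                patient_id=patient_id,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=f"G{chrom}_{pos % 997}",
                functional_class=fclass,
                channel96=channel,
                per_region=per_region,
            )
            truth.mutations_per_clone[clone].append(rec.key)
            expected_vaf[rec.key] = vaf_by_region
            records.append(rec)
    return PatientSim(
        patient_id=patient_id,
        tumour_site=tumour_site,
        truth=truth,
        records=records,
        regions=regions,
        segments=segments,
        expected_vaf=expected_vaf,
    )


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def _draw_signature_weights(
    rng, config: SimulationConfig, catalog: SignatureCatalog, sig16: bool
) -> dict[str, float]:
    others = [n for n in catalog.names if n != "Signature_16"]
    base = rng.dirichlet(np.ones(len(others)))
    if sig16:
        w16 = float(rng.uniform(*config.sig16_weight_range))
        weights = {n: float(b * (1 - w16)) for n, b in zip(others, base)}
        weights["Signature_16"] = w16
    else:
        weights = {n: float(b) for n, b in zip(others, base)}
        weights["Signature_16"] = 0.0
    return weights


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def simulate_patient(
    config: SimulationConfig,
    seed: int,
    patient_id: str = "P1",
    tumour_site: str = "oesophagus",
    sig16: bool | None = None,
    catalog: SignatureCatalog | None = None,
    signature_weights: dict[str, float] | None = None,
) -> PatientSim:
    """Simulate one multi-region tumour; deterministic under a fixed seed."""
    rng = np.random.default_rng(seed)
    catalog = catalog or default_catalog()
    if sig16 is None:
        sig16 = bool(rng.random() < config.p_sig16)
    weights = signature_weights or _draw_signature_weights(rng, config, catalog, sig16)
    return _simulate_tumour(
        config, rng, patient_id, tumour_site, "", weights, catalog, set()
    )


def simulate_dual_tumour(
    config: SimulationConfig,
    shared_clones: int,
    seed: int,
    patient_id: str = "P1",
    sig16: bool | None = None,
    catalog: SignatureCatalog | None = None,
    signature_weights: dict[str, float] | None = None,
) -> DualTumourSim:
    """Two tumours of one patient sharing zero clones or exactly one.

    With ``shared_clones=0`` the mutation sets are disjoint; with 1, one
    designated clone's mutations appear (with tumour-specific prevalences)
    in both tumours.
    """
    if shared_clones not in (0, 1):
        raise ValueError("shared_clones must be 0 or 1")
    rng = np.random.default_rng(seed)
    catalog = catalog or default_catalog()
    if sig16 is None:
        sig16 = bool(rng.random() < config.p_sig16)
    weights = signature_weights or _draw_signature_weights(rng, config, catalog, sig16)
    used_keys: set[str] = set()
    tumour_a = _simulate_tumour(
        config, rng, patient_id, "oesophagus", "E", weights, catalog, used_keys
    )
    tumour_b = _simulate_tumour(
        config, rng, patient_id, "hypopharynx", "H", weights, catalog, used_keys
    )
    shared_keys: set[str] = set()
    if shared_clones == 1:
        shared_keys = _insert_shared_clone(config, rng, tumour_a, tumour_b, catalog, weights)
    return DualTumourSim(
        patient_id=patient_id,
        tumour_a=tumour_a,
        tumour_b=tumour_b,
        shared_clones=shared_clones,
        shared_mutation_keys=shared_keys,
    )


def _insert_shared_clone(
    config, rng, tumour_a: PatientSim, tumour_b: PatientSim, catalog, weights
) -> set[str]:
    """Add one clone, with a single mutation set, to both tumours."""
    mixture = np.array([weights.get(n, 0.0) for n in catalog.names])
    channel_probs = catalog.matrix @ (mixture / mixture.sum())
    n_mut = int(rng.integers(*config.mutations_per_clone, endpoint=True))
    used = {r.key for r in tumour_a.records} | {r.key for r in tumour_b.records}
    sites = []
    for _ in range(n_mut):
        channel = int(rng.choice(96, p=channel_probs))
        sites.append(_draw_mutation_site(rng, used, channel, False) + (channel,))

    keys: set[str] = set()
    for tumour in (tumour_a, tumour_b):
        truth = tumour.truth
        cid = f"C{len(truth.clone_ids) + 1}"
        region_ids = [r.region_id for r in tumour.regions]
        occ = [r for r in region_ids if rng.random() < 0.7]
        if not occ:
            occ = [region_ids[rng.integers(len(region_ids))]]
        f_shared = float(rng.uniform(0.2, 0.5))
        truth.clone_ids.append(cid)
        truth.parent[cid] = "C1"
        truth.occupancy[cid] = occ
        truth.region_fractions[cid] = {}
        truth.mutations_per_clone[cid] = []
        for r in occ:
            for c in truth.clone_ids[:-1]:
                if r in truth.region_fractions[c]:
                    truth.region_fractions[c][r] *= 1 - f_shared
            truth.region_fractions[cid][r] = f_shared
        # recompute subtree CCFs after rescaling
        children: dict[str, list[str]] = {c: [] for c in truth.clone_ids}
        for c, p in truth.parent.items():
            if p is not None:
                children[p].append(c)

        def subtree(c, r):
            s = truth.region_fractions[c].get(r, 0.0)
            for ch in children[c]:
                s += subtree(ch, r)
            return s

        truth.ccf = {
            c: {r: subtree(c, r) for r in region_ids if r in truth.occupancy[c]}
            for c in truth.clone_ids
        }
        for chrom, pos, ref, alt, channel in sites:
            per_region: dict[str, tuple[int, int]] = {}
            vaf_by_region: dict[str, float] = {}
            for region in tumour.regions:
                rid = region.region_id
                ccf_val = truth.ccf[cid].get(rid, 0.0)
                rho = region.purity
                vaf = rho * ccf_val / (rho * 2 + (1 - rho) * 2)
                vaf_by_region[rid] = min(vaf, 1.0)
                depth = int(rng.poisson(config.depth_mean))
                alt_reads = int(rng.binomial(depth, min(vaf, 1.0))) if depth else 0
                per_region[rid] = (alt_reads, depth)
            rec = MutationRecord(
                patient_id=tumour.patient_id,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=f"G{chrom}_{pos % 997}",
                functional_class="nonsynonymous",
                channel96=channel,
                per_region=per_region,
            )
            truth.mutations_per_clone[cid].append(rec.key)
            tumour.expected_vaf[rec.key] = vaf_by_region
            tumour.records.append(rec)
            keys.add(rec.key)
    return keys


def simulate_cohort(
    config: SimulationConfig,
    seed: int | None = None,
    with_reads: bool = True,
    catalog: SignatureCatalog | None = None,
) -> CohortBundle:
    """Simulate a full cohort with clinical covariates tied to signature 16.

    Binary covariates (drinking, smoking, male, dual_primary, relapse,
    dead) are drawn conditionally on each patient's true signature-16
    status per ``config.covariate_model``. Patients drawn as dual-primary
    get two tumours (sharing 0 or 1 clones, equiprobable); the rest get a
    single tumour. ``with_reads=False`` skips read-level simulation and
    returns covariates only (for large association experiments).
    """
    seed = config.seed if seed is None else seed
    catalog = catalog or default_catalog()
    master = np.random.default_rng([seed, 0])
    rows = []
    patients: list = []
    weights_by_patient: dict[str, dict[str, float]] = {}
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        rng = _patient_rng(seed, i + 1)
        sig16 = bool(rng.random() < config.p_sig16)
        row = {"patient_id": pid, "sig16": int(sig16)}
        for name, (p1, p0) in config.covariate_model.items():
            row[name] = int(rng.random() < (p1 if sig16 else p0))
        rows.append(row)
        if with_reads:
            weights = _draw_signature_weights(rng, config, catalog, sig16)
            weights_by_patient[pid] = weights
            if row.get("dual_primary"):
                shared = int(master.integers(0, 2))
                sim = simulate_dual_tumour(
                    config, shared, seed=int(rng.integers(2**31)),
                    patient_id=pid, sig16=sig16, catalog=catalog,
                    signature_weights=weights,
                )
            else:
                sim = simulate_patient(
                    config, seed=int(rng.integers(2**31)),
                    patient_id=pid, sig16=sig16, catalog=catalog,
                    signature_weights=weights,
                )
            patients.append(sim)
    covariates = pd.DataFrame(rows).set_index("patient_id")
    return CohortBundle(
        config=config,
        seed=seed,
        patients=patients,
        covariates=covariates,
        signature_weights=weights_by_patient,
    )


def write_fixture(bundle: CohortBundle, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as MAF + SEG + region/covariate TSVs + truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records, regions, segments = [], [], []
    merged: dict[tuple[str, str], MutationRecord] = {}
    truth: dict[str, dict] = {}

    def add(sim: PatientSim, label: str):
        # a shared clone's mutations appear in both tumours of a dual
        # patient; merge their per-region counts into one MAF row
        for rec in sim.records:
            key = (rec.patient_id, rec.key)
            if key in merged:
                merged[key].per_region.update(rec.per_region)
            else:
                clone = MutationRecord(
                    patient_id=rec.patient_id, chrom=rec.chrom, pos=rec.pos,
                    ref=rec.ref, alt=rec.alt, gene=rec.gene,
                    functional_class=rec.functional_class,
                    channel96=rec.channel96,
                    per_region=dict(rec.per_region),
                )
                merged[key] = clone
                records.append(clone)
        regions.extend(sim.regions)
        segments.extend(sim.segments)
        truth[label] = {
            "clone_ids": sim.truth.clone_ids,
            "parent": sim.truth.parent,
            "mutations_per_clone": sim.truth.mutations_per_clone,
            "occupancy": sim.truth.occupancy,
            "region_fractions": sim.truth.region_fractions,
            "ccf": sim.truth.ccf,
        }

    for sim in bundle.patients:
        if isinstance(sim, DualTumourSim):
            add(sim.tumour_a, f"{sim.patient_id}:oesophagus")
            add(sim.tumour_b, f"{sim.patient_id}:hypopharynx")
            truth[f"{sim.patient_id}:shared"] = {
                "shared_clones": sim.shared_clones,
                "shared_mutation_keys": sorted(sim.shared_mutation_keys),
            }
        else:
            add(sim, sim.patient_id)

    paths = {
        "maf": directory / "mutations.maf",
        "seg": directory / "copynumber.seg",
        "regions": directory / "regions.tsv",
        "covariates": directory / "covariates.tsv",
        "truth": directory / "truth.json",
    }
    write_mutation_table(records, paths["maf"])
    write_seg(segments, paths["seg"])
    write_region_table(regions, paths["regions"])
    bundle.covariates.to_csv(paths["covariates"], sep="\t")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": bundle.seed,
                "config": {
                    k: v for k, v in asdict(bundle.config).items()
                },
                "patients": truth,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return paths


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
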