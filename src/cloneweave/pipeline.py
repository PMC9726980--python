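"""End-to-end orchestration: simulate/ingest -> signatures -> clonality ->
heterogeneity -> associations, with versioned, seed-stamped outputs.

The pipeline operates per tumour (a dual-primary patient contributes two),
then aggregates patient-level calls into the cohort covariate table for the
exact association tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import clonality as cl
from . import ith as ith_mod
from . import signatures as sig
from . import stats as st
from . import variants as vm
from .simulate import (
    CohortBundle,
    DualTumourSim,
    PatientSim,
    SimulationConfig,
    simulate_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    min_alt_reads: int = 3
    min_vaf: float = 0.05
    min_carcinoma_content: float = 0.30
    clonal_threshold: float = 0.9
    min_relative_exposure: float = 0.05
    min_region_fraction: float = 1 / 3
    ith_threshold: float = 0.5
    max_clones: int = 8
    n_restarts: int = 10


@dataclass
class RunConfig:
    """Pipeline run configuration (YAML-serialisable)."""

    out_dir: str = "cloneweave_run"
    seed: int = 0
    simulate: bool = True
    simulation: dict = field(default_factory=dict)
    maf: str | None = None
    seg: str | None = None
    regions: str | None = None
    covariates: str | None = None
    drivers: list[str] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class TumourAnalysis:
    patient_id: str
    tumour_site: str
    labels: list
    heterogeneity: float
    model: cl.CloneModel
    exposures: dict[str, sig.ExposureVector]
    sig16_present: bool
    subclonal_driver: tuple[float, int, int]
    ith_high: bool


def analyse_tumour(
    records: Sequence[vm.MutationRecord],
    regions: Sequence[vm.RegionSample],
    segments: Sequence[vm.CnvSegment] | None,
    catalog: sig.SignatureCatalog,
    thresholds: Thresholds,
    drivers: Sequence[str] | None = None,
    signature: str = "Signature_16",
    seed: int = 0,
) -> TumourAnalysis:
    """Run the full single-tumour analysis stack.

    Filters regions and non-silent mutations, builds the presence matrix,
    labels trunk/branch, fits per-region signature exposures, infers clones
    and computes the subclonal-driver-based high-ITH flag.
    """
    t = thresholds
    regions = vm.filter_regions(regions, t.min_carcinoma_content)
    nonsilent = vm.filter_nonsilent(records)
    matrix = vm.build_presence_matrix(
        nonsilent, regions, t.min_alt_reads, t.min_vaf
    )
    detected = {rec.key for rec in nonsilent if rec.key in set(matrix.mutations)}
    kept = [rec for rec in nonsilent if rec.key in detected]
    labels = ith_mod.classify_trunk_branch(matrix)
    het = ith_mod.heterogeneity_frequency(labels) if labels else 0.0

    # per-region spectra over mutations detected in that region
    exposures: dict[str, sig.ExposureVector] = {}
    for j, region in enumerate(regions):
        in_region = [
            rec for rec in kept
            if matrix.present[matrix.mutations.index(rec.key), j]
        ]
        spectrum = sig.count_spectrum(in_region)
        if spectrum.total > 0:
            exposures[region.region_id] = sig.fit_exposures(spectrum, catalog)
    sig16 = (
        sig.call_signature_presence(
            list(exposures.values()), signature,
            t.min_relative_exposure, t.min_region_fraction,
        )
        if exposures
        else False
    )

    model = cl.infer_clones_for_patient(
        kept, regions, segments,
        max_clones=t.max_clones, n_restarts=t.n_restarts, seed=seed,
    )

    estimates = cl.ccf_estimates(
        kept, regions, segments,
        t.min_alt_reads, t.min_vaf, t.clonal_threshold,
    )
    gene_of = {rec.key: rec.gene for rec in kept}
    gene_status: dict[str, list[str]] = {}
    for est in estimates:
        gene_status.setdefault(gene_of[est.mutation_key], []).append(est.status)
    driver_list = list(drivers) if drivers else sorted(gene_status)
    frac, num, den = ith_mod.subclonal_driver_fraction(driver_list, gene_status) \
        if driver_list else (0.0, 0, 0)
    return TumourAnalysis(
        patient_id=regions[0].patient_id if regions else "?",
        tumour_site=regions[0].tumour_site if regions else "?",
        labels=labels,
        heterogeneity=het,
        model=model,
        exposures=exposures,
        sig16_present=sig16,
        subclonal_driver=(frac, num, den),
        ith_high=ith_mod.ith_high_flag(frac, t.ith_threshold),
    )


def _group_inputs(records, regions, segments):
    """Group loaded inputs into (patient, site) tumours."""
    by_tumour: dict[tuple[str, str], dict] = {}
    region_site = {r.region_id: (r.patient_id, r.tumour_site) for r in regions}
    for r in regions:
        by_tumour.setdefault((r.patient_id, r.tumour_site), {
            "records": [], "regions": [], "segments": []
        })["regions"].append(r)
    for rec in records:
        sites = {
            region_site[rid] for rid in rec.per_region if rid in region_site
        }
        for key in sites:
            if key in by_tumour:
                by_tumour[key]["records"].append(rec)
    for seg in segments or []:
        key = region_site.get(seg.region_id)
        if key in by_tumour:
            by_tumour[key]["segments"].append(seg)
    return by_tumour


def run_pipeline(config: RunConfig) -> Path:
    """Execute the pipeline and write the report bundle.

    Outputs: per-patient heterogeneity TSV, clone-model JSON, exposures
    TSV, dual-tumour relationship table, association TSV and a markdown
    report, all stamped with the config digest and seed. Output
    directories are versioned, never overwritten.
    """
    out = Path(config.out_dir)
    version = 0
    while out.exists():
        version += 1
        out = Path(f"{config.out_dir}.{version}")
    out.mkdir(parents=True)
    stamp = f"# cloneweave config={config.digest()} seed={config.seed}\n"
    catalog = sig.default_catalog()

    covariates: pd.DataFrame | None = None
    if config.simulate:
        sim_cfg = SimulationConfig(**config.simulation)
        bundle = simulate_cohort(sim_cfg, seed=config.seed, catalog=catalog)
        tumours = []
        for sim in bundle.patients:
            if isinstance(sim, DualTumourSim):
                tumours.append(sim.tumour_a)
                tumours.append(sim.tumour_b)
            else:
                tumours.append(sim)
        covariates = bundle.covariates.copy()
        inputs = {
            (tum.patient_id, tum.tumour_site): {
                "records": tum.records,
                "regions": tum.regions,
                "segments": tum.segments,
            }
            for tum in tumours
        }
    else:
        if not (config.maf and config.regions):
            raise ValueError("non-simulated runs need maf and regions paths")
        records = vm.read_mutation_table(config.maf)
        regions = vm.read_region_table(config.regions)
        segments = vm.read_seg(config.seg) if config.seg else []
        inputs = _group_inputs(records, regions, segments)
        if config.covariates:
            covariates = pd.read_csv(config.covariates, sep="\t", index_col=0)

    analyses: dict[tuple[str, str], TumourAnalysis] = {}
    for key, data in sorted(inputs.items()):
        try:
            analyses[key] = analyse_tumour(
                data["records"], data["regions"], data["segments"],
                catalog, config.thresholds, config.drivers, seed=config.seed,
            )
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage 'analyse_tumour' failed for {key}: {exc}"
            ) from exc

    # per-patient summary (dual patients: ESCC tumour drives the ITH call)
    ith_rows = []
    for (pid, site), ana in analyses.items():
        ith_rows.append({
            "patient_id": pid,
            "tumour_site": site,
            "n_trunk": sum(l.label == "trunk" for l in ana.labels),
            "n_branch": sum(l.label != "trunk" for l in ana.labels),
            "heterogeneity_frequency": round(ana.heterogeneity, 4),
            "subclonal_driver_fraction": round(ana.subclonal_driver[0], 4),
            "subclonal_driver_n": ana.subclonal_driver[1],
            "subclonal_driver_total": ana.subclonal_driver[2],
            "ith_high": int(ana.ith_high),
            "sig16_present": int(ana.sig16_present),
            "n_clones": len(ana.model.clones),
        })
    ith_df = pd.DataFrame(ith_rows)
    _write_tsv(ith_df, out / "ith_summary.tsv", stamp)

    clones_payload = {
        f"{pid}:{site}": {
            "clones": ana.model.clones,
            "clonality": ana.model.clonality.to_dict(),
            "assignment": ana.model.assignment,
            "bic": ana.model.bic,
            "loglik_trace": ana.model.loglik_trace,
        }
        for (pid, site), ana in analyses.items()
    }
    (out / "clone_models.json").write_text(
        stamp + json.dumps(clones_payload, indent=1, sort_keys=True) + "\n"
    )

    expo_rows = []
    for (pid, site), ana in analyses.items():
        for rid, ev in ana.exposures.items():
            row = {"patient_id": pid, "tumour_site": site, "region_id": rid}
            row.update({
                name: round(float(x), 4)
                for name, x in zip(ev.names, ev.relative)
            })
            row["reconstruction_cosine"] = round(ev.reconstruction_cosine, 4)
            expo_rows.append(row)
    _write_tsv(pd.DataFrame(expo_rows), out / "exposures.tsv", stamp)

    rel_rows = []
    by_patient: dict[str, dict[str, TumourAnalysis]] = {}
    for (pid, site), ana in analyses.items():
        by_patient.setdefault(pid, {})[site] = ana
    for pid, sites in sorted(by_patient.items()):
        if len(sites) == 2:
            a, b = (sites["oesophagus"], sites["hypopharynx"])
            n_shared, label = cl.classify_clonal_relationship(a.model, b.model)
            rel_rows.append({
                "patient_id": pid, "n_shared_clones": n_shared, "label": label,
            })
    _write_tsv(pd.DataFrame(rel_rows), out / "clonal_relationships.tsv", stamp)

    assoc_df = pd.DataFrame()
    if covariates is not None:
        cohort = covariates.copy()
        # overwrite covariate-table calls with the pipeline's own where made
        called16 = {
            pid: int(any(
                sites[s].sig16_present for s in sites
            ))
            for pid, sites in by_patient.items()
        }
        ith_high = {
            pid: int(any(sites[s].ith_high for s in sites))
            for pid, sites in by_patient.items()
        }
        if called16:
            cohort["sig16_called"] = pd.Series(called16)
            cohort["ith_high"] = pd.Series(ith_high)
        assoc_df = associate_cohort(cohort)
        _write_tsv(assoc_df, out / "associations.tsv", stamp)

    report = [
        "# cloneweave run report",
        "",
        f"- config digest: `{config.digest()}`",
        f"- seed: {config.seed}",
        f"- tumours analysed: {len(analyses)}",
        f"- dual-primary patients: {len(rel_rows)}",
        "",
        "## Heterogeneity",
        "```",
        ith_df.to_string(index=False) if not ith_df.empty else "(none)",
        "```",
        "",
        "## Dual-tumour clonal relationships",
        "```",
        pd.DataFrame(rel_rows).to_string(index=False) if rel_rows else "(none)",
        "```",
        "",
        "## Associations",
        "```",
        assoc_df.to_string(index=False) if not assoc_df.empty else "(none)",
        "```",
        "",
    ]
    (out / "report.md").write_text(stamp + "\n".join(report) + "\n")
    logger.info("pipeline outputs written to %s", out)
    return out


DEFAULT_PAIRS = [
    ("sig16", "drinking"),
    ("sig16", "smoking"),
    ("sig16", "male"),
    ("sig16", "dual_primary"),
    ("sig16", "relapse"),
    ("sig16", "dead"),
    ("dual_primary", "relapse"),
    ("dual_primary", "dead"),
    ("ith_high", "relapse"),
    ("ith_high", "dead"),
]


def associate_cohort(
    cohort: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Fisher p and phi for each available factor pair in the cohort table."""
    if pairs is None:
        pairs = [
            (f1, f2) for f1, f2 in DEFAULT_PAIRS
            if f1 in cohort.columns and f2 in cohort.columns
        ]
    rows = []
    for f1, f2 in pairs:
        try:
            table = st.build_contingency(cohort, f1, f2)
            res = st.associate(table)
        except (ValueError, KeyError) as exc:
            logger.warning("association %s~%s skipped: %s", f1, f2, exc)
            continue
        rows.append({
            "factor1": f1, "factor2": f2,
            "a": table.a, "b": table.b, "c": table.c, "d": table.d,
            "p_fisher": round(res.p_fisher_two_sided, 6),
            "phi": None if res.phi is None else round(res.phi, 4),
            "odds_ratio": res.odds_ratio,
        })
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(stamp)
        df.to_csv(fh, sep="\t", index=False)
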