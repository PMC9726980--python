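# cloneweave

Multi-region tumour sequencing analysis for studies of intra-tumour
heterogeneity (ITH) and synchronous dual primary cancers: cancer-cell-fraction
(CCF) and clonality inference, trunk/branch mutation classification,
dual-tumour clonal-relationship calls, mutational-signature exposure fitting,
and exact cohort association statistics — together with a ground-truthed
synthetic multi-region cohort simulator so every stage can be validated
without access to restricted patient sequencing data.

The intended users are cancer-genomics analysts working with multi-region
whole-exome data (several spatially distinct biopsies per tumour, each with
per-variant read counts, tumour purity and copy-number segments), in
particular for cohorts mixing single primary tumours with synchronous dual
primaries (e.g. oesophageal squamous cell carcinoma with a second
hypopharyngeal tumour).

## What it computes

**Cancer cell fraction.** For each mutation, region-wise:

```
CCF = VAF * (rho * CNt + (1 - rho) * CNn) / (rho * m)
```

with purity `rho`, tumour/normal local total copy number `CNt`/`CNn`,
multiplicity `m` (mutated copies per cancer cell, estimated by rounding the
implied copy count), clipped to [0, 1.5]. A mutation is clonal in a region
when CCF ≥ 0.9 (configurable).

**Clonal architecture.** Mutations are clustered across regions by an EM fit
of a binomial mixture on raw read counts: cluster `k` has per-region CCF
`phi_kr` and alt reads are Binomial(depth, `phi_kr * c_r`), where `c_r`
converts CCF to expected VAF. The number of clones is selected by BIC over
K = 1..8. A clone is *dominant* in a region when its clonality exceeds 0.5.
Two tumours of one patient are compared by clone mutation identity: 0 matched
clones = "not clonal", 1 = "one subclone in common", ≥ 2 = "clonally related".

**Trunk/branch ITH.** A mutation detected in every retained region is an
early *trunk* mutation; otherwise a late *branch* mutation (private = one
region, shared branch = several). The heterogeneity frequency is
H = branch / (trunk + branch) over a patient's non-silent mutations. Region
phylogenies are perfect phylogenies of the presence patterns when compatible,
greedy maximum parsimony otherwise.

**Signatures.** 96-channel trinucleotide spectra (COSMIC channel order,
pyrimidine-strand collapsed) are refit against a catalogue by non-negative
least squares, `min ||s - C e||, e >= 0`; a signature is present for a
patient when its relative exposure reaches 5% in at least one third of the
patient's regions.

**Association statistics.** Exact two-sided Fisher tests (probability-mass
ordering by hypergeometric enumeration), phi coefficients for binary traits,
Benjamini–Hochberg q-values, a rank-based differential copy-number screen
between paired tumours, and two-proportion power calculations.

## Worked example

```python
from cloneweave import (
    SimulationConfig, simulate_patient, build_presence_matrix,
    classify_trunk_branch, heterogeneity_frequency,
    infer_clones_for_patient, ContingencyTable2x2,
    fisher_exact_two_sided, phi_coefficient,
)

cfg = SimulationConfig(depth_mean=150, regions_per_tumour=(5, 5))
patient = simulate_patient(cfg, seed=42)
print(f"true clones: {patient.truth.n_clones}, mutations: {len(patient.records)}")

matrix = build_presence_matrix(patient.records, patient.regions)
labels = classify_trunk_branch(matrix)
h = heterogeneity_frequency(labels)
n_trunk = sum(l.label == "trunk" for l in labels)
print(f"trunk: {n_trunk}, branch: {len(labels) - n_trunk}, "
      f"heterogeneity frequency: {h:.3f}")

model = infer_clones_for_patient(patient.records, patient.regions,
                                 patient.segments, seed=1)
print(f"inferred clones: {len(model.clones)}")
print(model.clonality.round(2))

table = ContingencyTable2x2(12, 1, 1, 4)  # signature-positive vs drinking
print(f"Fisher p = {fisher_exact_two_sided(table):.3f}, "
      f"phi = {phi_coefficient(table):.3f}")
```

prints

```
true clones: 6, mutations: 99
trunk: 26, branch: 73, heterogeneity frequency: 0.737
inferred clones: 6
    P1_R1  P1_R2  P1_R3  P1_R4  P1_R5
C1   1.00    1.0   1.00   1.00   1.00
C2   1.00    0.0   0.00   0.00   0.00
C3   0.00    0.0   0.00   0.85   0.00
C4   0.00    0.0   0.71   0.00   0.06
C5   0.61    0.0   0.00   0.00   0.00
C6   0.00    0.0   0.00   0.45   0.00
Fisher p = 0.008, phi = 0.723
```

The simulated tumour truly has six clones; the EM recovers all six, with
clone C1 (the trunk) fully clonal in every region. Of the 99 simulated
non-silent mutations, 73 are branch mutations, a heterogeneity frequency of
0.737. The 2×2 example shows a strong signature–drinking association
(p = 0.008, phi = 0.723).

## Command line

```
cloneweave simulate  --config cfg.yaml --out dir --seed N
cloneweave signatures --maf in.maf --catalog sigs.tsv --out exposures.tsv
cloneweave clonality --maf in.maf --seg cn.seg --meta regions.tsv --out clones.json
cloneweave ith       --maf in.maf --meta regions.tsv --out ith.tsv
cloneweave associate --cohort cohort.tsv --out assoc.tsv
cloneweave run       --config run.yaml
```

Input formats: MAF-like TSV (`Patient, Chrom, Pos, Ref, Alt, Gene, Class,
Channel96, <region>_alt, <region>_tot`), SEG copy-number segments, a region
metadata TSV (`patient_id, tumour_site, region_id, purity,
carcinoma_content`) and a tab-delimited 96×K signature catalogue.
VCF input with per-sample AD is also accepted for mutations.

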