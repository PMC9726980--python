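"""Mutational-signature spectra and non-negative exposure fitting.

An observed sample is summarised as a 96-channel trinucleotide substitution
spectrum ``s``; a catalogue ``C`` is a 96 x K column-stochastic matrix of
signature profiles. Exposures ``e >= 0`` are fitted by non-negative least
squares, minimising ``||s - C e||_2``, and the fit quality is reported as
the cosine similarity between the observed and reconstructed spectra.
Per-patient signature presence is called from per-region relative
exposures: a signature is present when its relative exposure reaches
``min_relative`` in at least ``min_region_fraction`` of the patient's
regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from ._channels import (
    CHANNEL_LABELS,
    N_CHANNELS,
    channel_index,
    parse_channel_label,
)
from .variants import MutationRecord

logger = logging.getLogger(__name__)


@dataclass
class Spectrum96:
    """96-channel substitution counts in conventional COSMIC channel order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_CHANNELS,):
            raise ValueError(f"spectrum must have {N_CHANNELS} channels")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __add__(self, other: "Spectrum96") -> "Spectrum96":
        return Spectrum96(self.counts + other.counts)


@dataclass
class SignatureCatalog:
    """Named collection of column-stochastic 96-channel signature profiles."""

    names: list[str]
    matrix: np.ndarray  # 96 x K

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (N_CHANNELS, len(self.names)):
            raise ValueError("catalogue matrix must be 96 x len(names)")
        if (self.matrix < 0).any():
            raise ValueError("catalogue entries must be non-negative")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("catalogue columns must each sum to 1 (+/- 1e-6)")

    @property
    def k(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureCatalog":
        """Load a tab-delimited catalogue (first column = channel labels).

        Rows may arrive in any order; they are re-indexed into the
        conventional channel order and validated for completeness.
        """
        df = pd.read_csv(path, sep="\t")
        labels = [str(v) for v in df.iloc[:, 0]]
        try:
            order = [parse_channel_label(lab) for lab in labels]
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from None
        if sorted(order) != list(range(N_CHANNELS)):
            raise ValueError(f"{path}: catalogue must cover all 96 channels once")
        matrix = np.zeros((N_CHANNELS, df.shape[1] - 1))
        matrix[order, :] = df.iloc[:, 1:].to_numpy(dtype=float)
        return cls(names=[str(c) for c in df.columns[1:]], matrix=matrix)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=self.names)
        df.insert(0, "Trinucleotide", list(CHANNEL_LABELS))
        df.to_csv(path, sep="\t", index=False)


@dataclass
class ExposureVector:
    """Non-negative signature contributions for one spectrum."""

    names: list[str]
    exposures: np.ndarray
    reconstruction_cosine: float

    def __post_init__(self) -> None:
        self.exposures = np.asarray(self.exposures, dtype=float)
        if (self.exposures < -1e-12).any():
            raise ValueError("exposures must be non-negative")
        self.exposures = np.clip(self.exposures, 0.0, None)

    @property
    def total(self) -> float:
        return float(self.exposures.sum())

    @property
    def relative(self) -> np.ndarray:
        t = self.total
        return self.exposures / t if t > 0 else np.zeros_like(self.exposures)

    def relative_of(self, name: str) -> float:
        return float(self.relative[self.names.index(name)])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def count_spectrum(
    records: Iterable[MutationRecord],
    fasta: str | Path | None = None,
) -> Spectrum96:
    """Tally single-base substitutions into a 96-channel spectrum.

    Records carrying a precomputed ``channel96`` are used directly;
    otherwise the trinucleotide context is read from ``fasta`` (pyfaidx)
    and the substitution is collapsed onto the pyrimidine strand. Indels
    are ignored; the total equals the number of contributing substitutions.
    """
    fa = None
    counts = np.zeros(N_CHANNELS)
    for rec in records:
        if not rec.is_snv:
            continue
        if rec.channel96 is not None:
            counts[rec.channel96] += 1
            continue
        if fasta is None:
            raise ValueError(
                f"{rec.key}: no channel96 and no reference FASTA to resolve context"
            )
        if fa is None:
            from pyfaidx import Fasta

            fa = Fasta(str(fasta))
        context = str(fa[rec.chrom][rec.pos - 2 : rec.pos + 1]).upper()
        counts[channel_index(rec.ref, rec.alt, context)] += 1
    return Spectrum96(counts)


def fit_exposures(spectrum: Spectrum96, catalog: SignatureCatalog) -> ExposureVector:
    """Non-negative least-squares refit of a spectrum against a catalogue.

    Returns the exposure vector ``e >= 0`` minimising ``||s - C e||`` and
    the cosine similarity between ``s`` and the reconstruction ``C e``.
    """
    if catalog.k == 0:
        raise ValueError("catalogue is empty")
    if spectrum.total <= 0:
        raise ValueError(
            "zero spectrum: no substitutions to fit; collect SNVs before fitting"
        )
    if np.linalg.matrix_rank(catalog.matrix) < catalog.k:
        warnings.warn(
            "rank-deficient signature catalogue; exposures may not be unique",
            stacklevel=2,
        )
    e, _ = nnls(catalog.matrix, spectrum.counts)
    recon = catalog.matrix @ e
    denom = np.linalg.norm(spectrum.counts) * np.linalg.norm(recon)
    cosine = float(spectrum.counts @ recon / denom) if denom > 0 else 0.0
    return ExposureVector(
        names=list(catalog.names),
        exposures=e,
        reconstruction_cosine=min(cosine, 1.0),
    )


def call_signature_presence(
    region_exposures: Sequence[ExposureVector],
    signature: str,
    min_relative: float = 0.05,
    min_region_fraction: float = 1 / 3,
) -> bool:
    """Patient-level presence call for one signature.

    Present iff the signature's relative exposure is >= ``min_relative`` in
    at least ``min_region_fraction`` of the patient's regions (both
    boundaries inclusive).
    """
    if not region_exposures:
        raise ValueError("at least one region exposure vector is required")
    for ev in region_exposures:
        if signature not in ev.names:
            raise KeyError(f"unknown signature id: {signature!r}")
    n_hit = sum(ev.relative_of(signature) >= min_relative for ev in region_exposures)
    return n_hit / len(region_exposures) >= min_region_fraction


def exposures_table(
    per_region: dict[str, ExposureVector],
) -> pd.DataFrame:
    """Relative exposures as a regions x signatures DataFrame."""
    rows = {rid: ev.relative for rid, ev in per_region.items()}
    names = next(iter(per_region.values())).names if per_region else []
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)


# ---------------------------------------------------------------------------
# Synthetic catalogues (no COSMIC download required)
# ---------------------------------------------------------------------------


def synthetic_orthogonal_catalog(k: int, seed: int = 0) -> SignatureCatalog:
    """Synthetic catalogue of K mutually orthogonal signatures.

    Each signature concentrates uniformly on its own disjoint block of
    96 // K channels, so exposures of mixtures are recoverable exactly;
    intended for tests and simulations.
    """
    if not 1 <= k <= N_CHANNELS:
        raise ValueError("k must be in 1..96")
    rng = np.random.default_rng(seed)
    blocks = np.array_split(rng.permutation(N_CHANNELS), k)
    matrix = np.zeros((N_CHANNELS, k))
    for j, block in enumerate(blocks):
        matrix[block, j] = 1.0 / len(block)
    return SignatureCatalog(names=[f"S{j + 1}" for j in range(k)], matrix=matrix)


#: Signature ids used by the bundled synthetic catalogue; the names mirror
#: the processes most often reported in oesophageal squamous tumours
#: (ageing, APOBEC, mismatch repair, UV-like, POLE, and the
#: alcohol-associated signature 16).
DEFAULT_SIGNATURE_NAMES = (
    "Signature_1",
    "Signature_2",
    "Signature_6",
    "Signature_7",
    "Signature_10",
    "Signature_13",
    "Signature_16",
)


def default_catalog(seed: int = 96) -> SignatureCatalog:
    """Bundled synthetic 96 x 7 catalogue (deterministic).

    Columns are sparse Dirichlet draws concentrated on distinct channel
    subsets, loosely mimicking the peaked shapes of real signatures. This is
    a synthetic stand-in generated in code, not COSMIC data.
    """
    rng = np.random.default_rng(seed)
    k = len(DEFAULT_SIGNATURE_NAMES)
    matrix = np.zeros((N_CHANNELS, k))
    for j in range(k):
        # ~12 dominant channels per signature plus a flat floor
        dominant = rng.choice(N_CHANNELS, size=12, replace=False)
        col = np.full(N_CHANNELS, 0.1 / N_CHANNELS)
        col[dominant] += rng.dirichlet(np.full(12, 0.6)) * 0.9
        matrix[:, j] = col / col.sum()
    return SignatureCatalog(names=list(DEFAULT_SIGNATURE_NAMES), matrix=matrix)
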