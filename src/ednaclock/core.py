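"""Domain types shared by every stage of the eDNA/eRNA decay pipeline.

The vocabulary mirrors a replicated mesocosm degradation experiment:
tanks hold a known number of organisms, water is sampled on a fixed
time grid after the organisms are removed, and each sample is assayed
by qPCR for several gene markers in both DNA and RNA form.  Markers
are labels with genomic metadata, never sequences.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple


class SchemaError(ValueError):
    """A required column or field is missing or misnamed."""


class ValidationError(ValueError):
    """Row- or field-level data that violates a domain invariant."""


class ConfigError(ValueError):
    """An invalid simulation or analysis configuration."""


class NotEstimableError(ValueError):
    """A quantity cannot be estimated from the data provided."""


class Genome(str, enum.Enum):
    """Genomic origin of a marker: mitochondrial or nuclear."""

    MT = "mt"
    NU = "nu"


class RnaClass(str, enum.Enum):
    """RNA type transcribed from the gene: ribosomal or messenger."""

    RRNA = "rRNA"
    MRNA = "mRNA"


class NucleicAcid(str, enum.Enum):
    """Whether the assayed molecule is DNA or (cDNA-quantified) RNA."""

    DNA = "DNA"
    RNA = "RNA"


#: Genes with a known (genome, RNA class) identity.  16S and COI are
#: mitochondrial (rRNA and mRNA respectively); 18S and the histone H2B
#: are nuclear (rRNA and mRNA).  Unknown gene prefixes are accepted with
#: any combination.
KNOWN_GENE_CLASSES: dict = {
    "16S": (Genome.MT, RnaClass.RRNA),
    "COI": (Genome.MT, RnaClass.MRNA),
    "18S": (Genome.NU, RnaClass.RRNA),
    "H2B": (Genome.NU, RnaClass.MRNA),
}


@dataclass(frozen=True)
class GeneTarget:
    """Identity of one qPCR marker.

    Parameters
    ----------
    name : str
        Short label, conventionally ``<gene>_<amplicon length>`` such as
        ``"16S_141"``.
    genome : Genome
        Mitochondrial (``mt``) or nuclear (``nu``) origin.
    rna_class : RnaClass
        RNA type of the gene (``rRNA`` or ``mRNA``); recorded for DNA
        assays too, as the classification of the underlying gene.
    amplicon_length : int
        Amplicon length in base pairs, > 0.
    nucleic_acid : NucleicAcid
        Whether the assay quantifies DNA or RNA.
    """

    name: str
    genome: Genome
    rna_class: RnaClass
    amplicon_length: int
    nucleic_acid: NucleicAcid

    def __post_init__(self) -> None:
        object.__setattr__(self, "genome", Genome(self.genome))
        object.__setattr__(self, "rna_class", RnaClass(self.rna_class))
        object.__setattr__(self, "nucleic_acid", NucleicAcid(self.nucleic_acid))
        if not self.name:
            raise ValidationError("GeneTarget.name must be non-empty")
        if int(self.amplicon_length) <= 0:
            raise ValidationError(
                f"amplicon_length must be positive, got {self.amplicon_length}"
            )
        object.__setattr__(self, "amplicon_length", int(self.amplicon_length))
        known = KNOWN_GENE_CLASSES.get(self.gene)
        if known is not None and (self.genome, self.rna_class) != known:
            raise ValidationError(
                f"gene {self.gene!r} is {known[0].value}/{known[1].value}; "
                f"got {self.genome.value}/{self.rna_class.value}"
            )

    @property
    def gene(self) -> str:
        """Gene symbol, the part of the name before the first underscore."""
        return self.name.split("_")[0]

    @property
    def key(self) -> Tuple[str, str]:
        """Identity key within a dataset: (name, nucleic acid)."""
        return (self.name, self.nucleic_acid.value)

    @property
    def label(self) -> str:
        return f"{self.name}_{self.nucleic_acid.value}"


@dataclass(frozen=True)
class Mesocosm:
    """One experimental tank: a known organism abundance and a replicate label."""

    tank_id: str
    abundance: int
    replicate: str = ""

    def __post_init__(self) -> None:
        if not self.tank_id:
            raise ValidationError("tank_id must be non-empty")
        if int(self.abundance) < 0:
            raise ValidationError(
                f"abundance must be >= 0 (0 = negative control), got {self.abundance}"
            )
        object.__setattr__(self, "abundance", int(self.abundance))


@dataclass(frozen=True)
class Measurement:
    """One qPCR-quantified water sample for one tank x target x time.

    A censored measurement (non-detect: the assay failed to amplify or
    amplified above the Cq threshold) carries no concentration;
    ``censored is True`` if and only if ``copies_per_ml is None``.
    """

    tank_id: str
    target: GeneTarget
    time_h: float
    copies_per_ml: Optional[float] = None
    censored: bool = False

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValidationError(f"time_h must be >= 0, got {self.time_h}")
        if self.censored:
            if self.copies_per_ml not in (None,):
                raise ValidationError(
                    "censored measurement must not carry a concentration"
                )
        else:
            if self.copies_per_ml is None:
                raise ValidationError(
                    "detected measurement must carry copies_per_ml"
                )
            if not math.isfinite(self.copies_per_ml) or self.copies_per_ml < 0:
                raise ValidationError(
                    f"copies_per_ml must be finite and >= 0, got {self.copies_per_ml}"
                )


@dataclass(frozen=True)
class ConcentrationSeries:
    """One tank x target time course, ordered by strictly increasing time.

    ``sample`` distinguishes nested replicate water samples drawn from
    the same tank at the same timepoints; the default design takes a
    single sample per tank per timepoint.
    """

    tank_id: str
    target: GeneTarget
    measurements: Tuple[Measurement, ...]
    abundance: Optional[int] = None
    replicate: str = ""
    sample: str = "s1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        for m in self.measurements:
            if m.tank_id != self.tank_id or m.target != self.target:
                raise ValidationError(
                    "all measurements in a series must share tank_id and target"
                )
        times = [m.time_h for m in self.measurements]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                f"series {self.tank_id}/{self.target.label}: time_h must be "
                "strictly increasing (use distinct 'sample' labels for nested "
                "replicate samples)"
            )

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def times(self) -> Tuple[float, ...]:
        return tuple(m.time_h for m in self.measurements)

    def detections(self) -> Tuple[Measurement, ...]:
        return tuple(m for m in self.measurements if not m.censored)

    def at_time(self, time_h: float) -> Optional[Measurement]:
        for m in self.measurements:
            if m.time_h == time_h:
                return m
        return None


@dataclass(frozen=True)
class KineticParams:
    """First-order decay parameters of one target: C(t) = exp(c0_log) * e^(-k t).

    ``k`` is stored as a non-negative magnitude in 1/h; the model applies
    the negative sign.  ``k=None`` marks a target whose decay constant is
    unknown (e.g. quantified too rarely to fit).
    """

    c0_log: float
    k: Optional[float] = None
    se_k: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.c0_log):
            raise ValidationError("c0_log must be finite")
        if self.k is not None and (not math.isfinite(self.k) or self.k < 0):
            raise ValidationError(f"k must be a non-negative magnitude, got {self.k}")
        if self.se_k is not None and self.se_k < 0:
            raise ValidationError("se_k must be >= 0")
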