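"""Core containers for replicated microsatellite (STR) genotype data.

Alleles are raw fragment lengths in base pairs (positive integers).  A PCR
replicate either fails to amplify or yields an unordered diploid genotype;
the consensus over replicates is stored per sample x locus in a
:class:`GenotypeMatrix`, which feeds all downstream population genetics.
Missing data is an explicit ``None`` state, never a sentinel number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import pandas as pd

__all__ = [
    "AllelePair",
    "ReplicateRecord",
    "ReplicateTable",
    "GenotypeMatrix",
]


@dataclass(frozen=True, order=True)
class AllelePair:
    """Unordered diploid genotype, stored as a sorted pair of bp lengths.

    The constructor sorts the two alleles, so ``AllelePair(125, 121)`` and
    ``AllelePair(121, 125)`` compare equal.
    """

    a: int
    b: int

    def __post_init__(self) -> None:
        if int(self.a) != self.a or int(self.b) != self.b:
            raise ValueError(f"alleles must be integers, got ({self.a!r}, {self.b!r})")
        object.__setattr__(self, "a", int(self.a))
        object.__setattr__(self, "b", int(self.b))
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"allele lengths must be positive, got ({self.a}, {self.b})")
        if self.a > self.b:
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @property
    def alleles(self) -> Tuple[int, int]:
        return (self.a, self.b)

    @property
    def homozygous(self) -> bool:
        return self.a == self.b

    @property
    def heterozygous(self) -> bool:
        return self.a != self.b

    @property
    def shorter(self) -> int:
        return self.a

    @property
    def longer(self) -> int:
        return self.b

    def __contains__(self, allele: int) -> bool:
        return allele == self.a or allele == self.b

    def __iter__(self) -> Iterator[int]:
        return iter((self.a, self.b))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.a}/{self.b}"


@dataclass(frozen=True)
class ReplicateRecord:
    """One PCR replicate of one sample at one locus.

    ``genotype is None`` marks an amplification failure (negative PCR); a
    half-called outcome does not exist at this level — readers reject it.
    """

    sample_id: str
    population_id: str
    locus_id: str
    replicate_index: int
    genotype: Optional[AllelePair]

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be a positive integer")

    @property
    def failed(self) -> bool:
        return self.genotype is None

    @property
    def positive(self) -> bool:
        return self.genotype is not None

    @property
    def key(self) -> Tuple[str, str, int]:
        return (self.sample_id, self.locus_id, self.replicate_index)


class ReplicateTable:
    """Collection of :class:`ReplicateRecord` with locus order and a population map.

    Records are indexed by (sample, locus) for consensus calling and by the
    full (sample, locus, replicate) key, which must be unique.
    """

    def __init__(
        self,
        records: Iterable[ReplicateRecord],
        loci: Optional[List[str]] = None,
        populations: Optional[Mapping[str, str]] = None,
    ) -> None:
        self.records: List[ReplicateRecord] = list(records)
        seen_loci: List[str] = []
        pops: Dict[str, str] = {}
        keys = set()
        index: Dict[Tuple[str, str], List[ReplicateRecord]] = {}
        samples: List[str] = []
        for rec in self.records:
            if rec.key in keys:
                raise ValueError(f"duplicate replicate key {rec.key}")
            keys.add(rec.key)
            if rec.locus_id not in index and rec.locus_id not in seen_loci:
                seen_loci.append(rec.locus_id)
            prev = pops.setdefault(rec.sample_id, rec.population_id)
            if prev != rec.population_id:
                raise ValueError(
                    f"sample {rec.sample_id!r} assigned to populations "
                    f"{prev!r} and {rec.population_id!r}"
                )
            if rec.sample_id not in index or (rec.sample_id, rec.locus_id) not in index:
                pass
            index.setdefault((rec.sample_id, rec.locus_id), []).append(rec)
            if rec.sample_id not in samples:
                samples.append(rec.sample_id)
        self.loci: List[str] = list(loci) if loci is not None else seen_loci
        unknown = {r.locus_id for r in self.records} - set(self.loci)
        if unknown:
            raise ValueError(f"records reference loci not in locus list: {sorted(unknown)}")
        self.populations: Dict[str, str] = dict(populations) if populations else pops
        missing_pop = [s for s in samples if s not in self.populations]
        if missing_pop:
            raise ValueError(f"samples without population assignment: {missing_pop}")
        self.samples: List[str] = samples
        self._index = index

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReplicateRecord]:
        return iter(self.records)

    def replicates(self, sample_id: str, locus_id: str) -> List[ReplicateRecord]:
        """All replicates of one sample at one locus (possibly empty)."""
        return list(self._index.get((sample_id, locus_id), []))

    def get(self, sample_id: str, locus_id: str, replicate_index: int) -> ReplicateRecord:
        for rec in self._index.get((sample_id, locus_id), []):
            if rec.replicate_index == replicate_index:
                return rec
        raise KeyError((sample_id, locus_id, replicate_index))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per replicate (failures have NA alleles)."""
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "sample": rec.sample_id,
                    "population": rec.population_id,
                    "locus": rec.locus_id,
                    "replicate": rec.replicate_index,
                    "allele1": rec.genotype.a if rec.genotype else pd.NA,
                    "allele2": rec.genotype.b if rec.genotype else pd.NA,
                }
            )
        return pd.DataFrame(
            rows, columns=["sample", "population", "locus", "replicate", "allele1", "allele2"]
        )


class GenotypeMatrix:
    """Consensus genotypes per sample x locus, with sample -> population map.

    ``entries[(sample, locus)]`` is an :class:`AllelePair` or ``None`` for a
    missing (undetermined) genotype.  All samples share the same locus list.
    """

    def __init__(
        self,
        entries: Mapping[Tuple[str, str], Optional[AllelePair]],
        populations: Mapping[str, str],
        loci: Iterable[str],
    ) -> None:
        self.loci: List[str] = list(loci)
        locus_set = set(self.loci)
        self.entries: Dict[Tuple[str, str], Optional[AllelePair]] = {}
        samples: List[str] = []
        for (sample, locus), pair in entries.items():
            if locus not in locus_set:
                raise ValueError(f"entry references unknown locus {locus!r}")
            self.entries[(sample, locus)] = pair
            if sample not in samples:
                samples.append(sample)
        self.samples: List[str] = samples
        self.populations: Dict[str, str] = dict(populations)
        missing = [s for s in samples if s not in self.populations]
        if missing:
            raise ValueError(f"samples without population assignment: {missing}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def population_ids(self) -> List[str]:
        """Populations in order of first appearance among samples."""
        out: List[str] = []
        for s in self.samples:
            p = self.populations[s]
            if p not in out:
                out.append(p)
        return out

    def samples_in(self, population_id: str) -> List[str]:
        return [s for s in self.samples if self.populations[s] == population_id]

    def genotype(self, sample_id: str, locus_id: str) -> Optional[AllelePair]:
        """Genotype at a cell; ``None`` if missing or the cell is absent."""
        return self.entries.get((sample_id, locus_id))

    def typed_genotypes(self, population_id: str, locus_id: str) -> List[AllelePair]:
        """Non-missing genotypes of one population at one locus."""
        out = []
        for s in self.samples_in(population_id):
            g = self.entries.get((s, locus_id))
            if g is not None:
                out.append(g)
        return out

    def observed_alleles(self, locus_id: str, populations: Optional[Iterable[str]] = None):
        """Set of allele lengths observed at a locus (optionally restricted)."""
        pops = set(populations) if populations is not None else None
        alleles = set()
        for (sample, locus), pair in self.entries.items():
            if locus != locus_id or pair is None:
                continue
            if pops is not None and self.populations[sample] not in pops:
                continue
            alleles.update(pair.alleles)
        return alleles

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sample in self.samples:
            row = {"sample": sample, "population": self.populations[sample]}
            for locus in self.loci:
                g = self.entries.get((sample, locus))
                row[f"{locus}.1"] = g.a if g else pd.NA
                row[f"{locus}.2"] = g.b if g else pd.NA
            rows.append(row)
        return pd.DataFrame(rows)
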