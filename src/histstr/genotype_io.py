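"""Readers and writers for replicate tables and downstream genotype formats.

Input is delimited text (comma or tab, autodetected) with one PCR replicate
per row.  Consensus matrices can be exported to the two formats the field's
standard tools consume — GenAlEx codominant CSV and the STRUCTURE two-row
layout — and pairwise distance matrices to PHYLIP square format (the input
SplitsTree expects).
"""

from __future__ import annotations

import csv
import warnings
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .types import AllelePair, GenotypeMatrix, ReplicateRecord, ReplicateTable

__all__ = [
    "ReplicateTableError",
    "read_replicate_table",
    "write_replicate_table",
    "read_consensus_table",
    "write_genalex",
    "write_structure",
    "write_phylip_distance",
]

#: canonical column names; a dialect maps these onto the file's own headers
CANONICAL_COLUMNS = ("sample", "population", "locus", "replicate", "allele1", "allele2")

#: cell values (case-insensitive) that mean "no allele called"
MISSING_TOKENS = {"", "na", "nan", "none", ".", "-", "0", "-9"}


class ReplicateTableError(ValueError):
    """Raised when a replicate table file is ill-formed; carries row numbers."""


def _is_missing(cell: object) -> bool:
    if cell is None:
        return True
    text = str(cell).strip().lower()
    return text in MISSING_TOKENS


def _parse_allele(cell: object, row_number: int, errors: List[str]) -> Optional[int]:
    text = str(cell).strip()
    try:
        value = int(text)
    except ValueError:
        errors.append(f"row {row_number}: non-integer allele {text!r}")
        return None
    if value <= 0:
        errors.append(f"row {row_number}: non-positive allele {value}")
        return None
    return value


def read_replicate_table(
    path, dialect: Optional[Mapping[str, str]] = None
) -> ReplicateTable:
    """Read a replicated per-PCR genotype table from delimited text.

    Parameters
    ----------
    path : path-like
        File with one PCR replicate per row and a header line.  The delimiter
        (comma or tab) is autodetected.
    dialect : mapping, optional
        Map from the canonical column names ``sample, population, locus,
        replicate, allele1, allele2`` to the file's actual headers, so e.g.
        GeneMapper-style exports can be adapted without code changes.

    Returns
    -------
    ReplicateTable

    Raises
    ------
    ReplicateTableError
        If columns are unresolvable, a (sample, locus, replicate) key is
        duplicated, an allele is non-integer, or a row is half-called (one
        allele present, one absent).  The error message lists the offending
        rows; rejected rows are never silently dropped.
    """
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    colmap = {c: c for c in CANONICAL_COLUMNS}
    if dialect:
        colmap.update(dialect)
    lower = {str(c).strip().lower(): c for c in frame.columns}
    resolved: Dict[str, str] = {}
    missing_cols = []
    for canon in CANONICAL_COLUMNS:
        wanted = colmap[canon].strip().lower()
        if wanted in lower:
            resolved[canon] = lower[wanted]
        else:
            missing_cols.append(colmap[canon])
    if missing_cols:
        raise ReplicateTableError(f"cannot resolve columns {missing_cols} in {list(frame.columns)}")

    errors: List[str] = []
    records: List[ReplicateRecord] = []
    seen: Dict[Tuple[str, str, int], int] = {}
    for i in range(len(frame)):
        rownum = i + 2  # 1-based, after the header line
        cells = {canon: frame.iloc[i][resolved[canon]] for canon in CANONICAL_COLUMNS}
        sample = str(cells["sample"]).strip()
        population = str(cells["population"]).strip()
        locus = str(cells["locus"]).strip()
        try:
            replicate = int(str(cells["replicate"]).strip())
        except ValueError:
            errors.append(f"row {rownum}: non-integer replicate index {cells['replicate']!r}")
            continue
        m1, m2 = _is_missing(cells["allele1"]), _is_missing(cells["allele2"])
        if m1 != m2:
            errors.append(
                f"row {rownum}: half-called genotype "
                f"({cells['allele1']!r}, {cells['allele2']!r})"
            )
            continue
        if m1 and m2:
            genotype = None
        else:
            a = _parse_allele(cells["allele1"], rownum, errors)
            b = _parse_allele(cells["allele2"], rownum, errors)
            if a is None or b is None:
                continue
            genotype = AllelePair(a, b)
        key = (sample, locus, replicate)
        if key in seen:
            errors.append(f"row {rownum}: duplicate key {key} (first at row {seen[key]})")
            continue
        seen[key] = rownum
        records.append(ReplicateRecord(sample, population, locus, replicate, genotype))
    if errors:
        raise ReplicateTableError("; ".join(errors))
    return ReplicateTable(records)


def write_replicate_table(table: ReplicateTable, path) -> None:
    """Write a replicate table in the canonical delimited layout (CSV).

    Failures are written with empty allele cells; :func:`read_replicate_table`
    on the output is the identity.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANONICAL_COLUMNS)
        for rec in table.records:
            if rec.genotype is None:
                a1 = a2 = ""
            else:
                a1, a2 = rec.genotype.a, rec.genotype.b
            writer.writerow(
                [rec.sample_id, rec.population_id, rec.locus_id, rec.replicate_index, a1, a2]
            )


def write_genalex(matrix: GenotypeMatrix, path, title: str = "histstr export") -> None:
    """Write a consensus matrix in GenAlEx codominant CSV layout.

    Three header rows (counts, title + population labels, column labels)
    followed by one row per sample with two columns per locus; missing
    alleles are encoded ``0`` (the GenAlEx convention).
    """
    if not matrix.entries:
        raise ValueError("cannot write an empty matrix")
    pops = matrix.population_ids
    sizes = [len(matrix.samples_in(p)) for p in pops]
    n_loci = len(matrix.loci)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([n_loci, len(matrix.samples), len(pops), *sizes])
        writer.writerow([title, "", "", *pops])
        header = ["Sample", "Pop"]
        for locus in matrix.loci:
            header.extend([locus, ""])
        writer.writerow(header)
        for sample in matrix.samples:
            row: List[object] = [sample, matrix.populations[sample]]
            for locus in matrix.loci:
                g = matrix.genotype(sample, locus)
                row.extend([g.a, g.b] if g is not None else [0, 0])
            writer.writerow(row)


def write_structure(matrix: GenotypeMatrix, path) -> None:
    """Write a consensus matrix in the STRUCTURE two-row format.

    Each sample occupies two whitespace-delimited rows (one allele copy per
    row): sample label, integer population index (1-based, order of first
    appearance), then one allele per locus.  Missing alleles are ``-9``.
    """
    if not matrix.entries:
        raise ValueError("cannot write an empty matrix")
    pop_index = {p: i + 1 for i, p in enumerate(matrix.population_ids)}
    with open(path, "w") as fh:
        for sample in matrix.samples:
            for copy in (0, 1):
                fields = [sample, str(pop_index[matrix.populations[sample]])]
                for locus in matrix.loci:
                    g = matrix.genotype(sample, locus)
                    fields.append(str(g.alleles[copy]) if g is not None else "-9")
                fh.write("\t".join(fields) + "\n")


def write_phylip_distance(dm, path) -> None:
    """Write a distance matrix in PHYLIP square format.

    Negative estimates (legitimate for unbiased differentiation estimators)
    are clamped to 0 with a warning, because SplitsTree rejects negative
    branch input.  Asymmetric matrices are rejected.
    """
    values = np.asarray(dm.values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (values < 0).any():
        warnings.warn(
            "negative distance estimates clamped to 0 for PHYLIP export",
            UserWarning,
            stacklevel=2,
        )
        values = np.clip(values, 0.0, None)
    labels = list(dm.labels)
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for label, row in zip(labels, values):
            fh.write(f"{label:<10} " + " ".join(f"{v:.6f}" for v in row) + "\n")


def write_consensus_table(calls, populations: Mapping[str, str], path, decisions=None) -> None:
    """Write per sample x locus consensus calls as delimited text.

    Columns: sample, population, locus, allele1, allele2, qi, n_positive,
    n_replicates, decision.  Undetermined genotypes have empty allele cells.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample", "population", "locus", "allele1", "allele2",
             "qi", "n_positive", "n_replicates", "decision"]
        )
        for call in calls:
            g = call.genotype
            verdict = ""
            if decisions is not None and call.sample_id in decisions:
                verdict = decisions[call.sample_id].verdict
            writer.writerow(
                [
                    call.sample_id,
                    populations[call.sample_id],
                    call.locus_id,
                    g.a if g else "",
                    g.b if g else "",
                    "" if call.qi is None else f"{call.qi:.6g}",
                    call.n_positive,
                    call.n_replicates,
                    verdict,
                ]
            )


def read_consensus_table(path, accepted_only: bool = True) -> GenotypeMatrix:
    """Rebuild a :class:`GenotypeMatrix` from a written consensus table.

    With ``accepted_only`` (default) samples whose decision column is present
    and not ``accept`` are excluded, mirroring the genotyping workflow.
    """
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    entries: Dict[Tuple[str, str], Optional[AllelePair]] = {}
    populations: Dict[str, str] = {}
    loci: List[str] = []
    for _, row in frame.iterrows():
        verdict = str(row.get("decision", "")).strip()
        if accepted_only and verdict and verdict != "accept":
            continue
        sample, pop, locus = row["sample"], row["population"], row["locus"]
        populations[sample] = pop
        if locus not in loci:
            loci.append(locus)
        if _is_missing(row["allele1"]) or _is_missing(row["allele2"]):
            entries[(sample, locus)] = None
        else:
            entries[(sample, locus)] = AllelePair(int(row["allele1"]), int(row["allele2"]))
    return GenotypeMatrix(entries, populations, loci)
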