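"""Data model and I/O for co-dominant SSR genotype panels.

A genotype panel is a diploid individuals-by-loci table whose cells hold an
unordered pair of allele labels (PCR fragment sizes in bp) or a missing
marker.  Alongside it live a marker map (linkage group, genetic position in
cM, physical position in bp on a named scaffold) and per-sample metadata
(origin, breeding status).  Every downstream statistic works from allele
frequencies computed here with per-locus ("pairwise") deletion of missing
calls, so per-locus sample sizes may differ.

Missing-data codes follow the de facto dialect conventions: ``.`` in the
native TSV, ``-9`` in the two-row STRUCTURE layout, ``0`` in the GenAlEx-like
layout.  Internally a single sentinel (:data:`MISSING`) is used.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "MarkerMap",
    "SampleMetadata",
    "AlleleFrequencyTable",
    "GenodataError",
    "ParseError",
    "ValidationError",
    "read_genotype_table",
    "write_genotype_table",
    "allele_frequencies",
    "recode_rare_alleles",
    "thin_markers",
    "subset",
    "load_packaged_marker_map",
    "load_packaged_locus_table",
    "load_packaged_ld_summary",
    "read_marker_map",
    "write_marker_map",
    "read_metadata",
    "write_metadata",
]

#: Internal sentinel for a missing diploid call (stored in both array slots).
MISSING = -1

#: Allowed breeding-status vocabulary for sample metadata.
STATUS_VOCABULARY = ("wild", "landrace", "breeding")


class GenodataError(ValueError):
    """Base class for genotype-data errors."""


class ParseError(GenodataError):
    """A file did not parse under the requested dialect."""


class ValidationError(GenodataError):
    """Parsed content violates a data-model invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for ``individuals`` x ``loci``.

    ``calls`` has shape (N, L, 2) with integer allele labels (fragment sizes);
    a missing cell carries :data:`MISSING` in both slots.  The pair is
    unordered; calls are stored sorted so equality is well defined.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = list(self.individuals)
        self.loci = list(self.loci)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        for name, ids in (("individual", self.individuals), ("locus", self.loci)):
            if any(not i for i in ids):
                raise ValidationError(f"empty {name} identifier")
            if len(set(ids)) != len(ids):
                dup = next(i for i in ids if ids.count(i) > 1)
                raise ValidationError(f"duplicate {name} identifier: {dup!r}")
        # normalize: sort each pair, force full-cell missingness
        miss = np.any(self.calls == MISSING, axis=2)
        self.calls = np.sort(self.calls, axis=2)
        self.calls[miss] = MISSING

    # -- basic accessors ----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus: {locus!r}") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean (N, L) mask of missing cells."""
        return self.calls[:, :, 0] == MISSING

    def locus_calls(self, locus: str) -> np.ndarray:
        """Non-missing (n_l, 2) calls at ``locus``."""
        j = self.locus_index(locus)
        col = self.calls[:, j, :]
        return col[col[:, 0] != MISSING]

    def sample_sizes(self) -> pd.Series:
        """Per-locus non-missing sample size n_l."""
        return pd.Series((~self.missing_mask()).sum(axis=0), index=self.loci, name="n")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class MarkerMap:
    """Per-locus map positions: linkage group (1-8 in peach), cM, scaffold, bp.

    Wraps a DataFrame indexed by locus id with columns ``linkage_group``
    (int), ``cm`` (float, NaN if unmapped), ``scaffold`` (str), ``bp``
    (float, NaN if unplaced).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"locus mapped twice: {dup!r}")
        for col in ("linkage_group", "cm", "scaffold", "bp"):
            if col not in df.columns:
                raise ValidationError(f"marker map missing column {col!r}")
        self.table = df

    @property
    def loci(self) -> list[str]:
        return list(self.table.index)

    def linkage_group(self, locus: str) -> int:
        return int(self.table.at[locus, "linkage_group"])

    def cm_distance(self, a: str, b: str) -> float:
        """|cM difference|; defined only for loci on the same linkage group."""
        ta, tb = self.table.loc[a], self.table.loc[b]
        if int(ta["linkage_group"]) != int(tb["linkage_group"]):
            return float("nan")
        if pd.isna(ta["cm"]) or pd.isna(tb["cm"]):
            return float("nan")
        return abs(float(ta["cm"]) - float(tb["cm"]))

    def kbp_distance(self, a: str, b: str) -> float:
        """|bp difference| / 1000; defined only on a shared scaffold."""
        ta, tb = self.table.loc[a], self.table.loc[b]
        if ta["scaffold"] != tb["scaffold"] or pd.isna(ta["bp"]) or pd.isna(tb["bp"]):
            return float("nan")
        return abs(float(ta["bp"]) - float(tb["bp"])) / 1000.0


@dataclass
class SampleMetadata:
    """Per-individual origin group, breeding status and collection."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        for col in ("origin", "status", "collection"):
            if col not in df.columns:
                raise ValidationError(f"metadata missing column {col!r}")
        bad = set(df["status"]) - set(STATUS_VOCABULARY)
        if bad:
            raise ValidationError(
                f"status values {sorted(bad)} outside vocabulary {STATUS_VOCABULARY}"
            )

    def groups(self, by: str = "origin") -> dict[str, list[str]]:
        """Individual ids grouped by a metadata column."""
        return {
            str(k): list(v.index) for k, v in self.table.groupby(by, sort=False)
        }


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies over non-missing calls.

    ``freqs[locus]`` maps allele label -> frequency (sums to 1 per locus);
    ``n[locus]`` is the non-missing sample size n_l in individuals.
    """

    freqs: dict[str, dict[int, float]]
    n: dict[str, int]

    def frequency(self, locus: str, allele: int) -> float:
        return self.freqs[locus].get(allele, 0.0)

    def major_allele_frequency(self, locus: str) -> float:
        return max(self.freqs[locus].values())


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _parse_allele(tok: str, line_no: int) -> int:
    try:
        return int(tok)
    except ValueError:
        raise ParseError(f"line {line_no}: non-integer allele label {tok!r}") from None


def _read_tsv(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "id":
            raise ParseError(f"line 1: expected header 'id<TAB>locus...', got {header[:2]}")
        loci = header[1:]
        individuals: list[str] = []
        rows: list[list[tuple[int, int]]] = []
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"line {line_no}: expected {len(header)} fields, got {len(parts)}"
                )
            individuals.append(parts[0])
            row = []
            for cell in parts[1:]:
                if cell == ".":
                    row.append((MISSING, MISSING))
                else:
                    try:
                        a, b = cell.split("/")
                    except ValueError:
                        raise ParseError(
                            f"line {line_no}: malformed cell {cell!r} (want 'a/b' or '.')"
                        ) from None
                    row.append((_parse_allele(a, line_no), _parse_allele(b, line_no)))
            rows.append(row)
    if not individuals:
        raise ParseError("no genotype rows")
    return GenotypeMatrix(individuals, loci, np.array(rows, dtype=np.int64))


def _write_tsv(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(g.loci) + "\n")
        for i, ind in enumerate(g.individuals):
            cells = []
            for j in range(g.n_loci):
                a, b = g.calls[i, j]
                cells.append("." if a == MISSING else f"{a}/{b}")
            fh.write(ind + "\t" + "\t".join(cells) + "\n")


def _read_structure(path: Path) -> GenotypeMatrix:
    """Two-rows-per-individual STRUCTURE layout, -9 for missing."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        loci = [h for h in header if h]
        lines = [ln.rstrip("\n").split("\t") for ln in fh if ln.strip()]
    if len(lines) % 2:
        raise ParseError(f"odd number of genotype rows ({len(lines)}) for two-row layout")
    individuals: list[str] = []
    calls = []
    for k in range(0, len(lines), 2):
        r1, r2 = lines[k], lines[k + 1]
        line_no = k + 2
        if r1[0] != r2[0]:
            raise ParseError(
                f"line {line_no + 1}: row pair ids differ ({r1[0]!r} vs {r2[0]!r})"
            )
        if len(r1) != len(loci) + 1 or len(r2) != len(loci) + 1:
            raise ParseError(f"line {line_no}: expected {len(loci) + 1} fields")
        individuals.append(r1[0])
        a = [_parse_allele(t, line_no) for t in r1[1:]]
        b = [_parse_allele(t, line_no + 1) for t in r2[1:]]
        cell = np.stack([a, b], axis=1)
        cell[np.any(cell == -9, axis=1)] = MISSING
        calls.append(cell)
    return GenotypeMatrix(individuals, loci, np.stack(calls))


def _write_structure(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(g.loci) + "\n")
        for i, ind in enumerate(g.individuals):
            for copy in range(2):
                toks = []
                for j in range(g.n_loci):
                    a = g.calls[i, j, copy]
                    toks.append("-9" if a == MISSING else str(a))
                fh.write(ind + "\t" + "\t".join(toks) + "\n")


def _read_genalex(path: Path) -> GenotypeMatrix:
    """GenAlEx-like layout: two columns per locus, 0 for missing."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "id" or (len(header) - 1) % 2:
            raise ParseError("line 1: expected 'id' plus two columns per locus")
        loci = header[1::2]
        if header[2::2] != loci:
            raise ParseError("line 1: paired locus columns must repeat the locus name")
        individuals = []
        calls = []
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(f"line {line_no}: expected {len(header)} fields")
            individuals.append(parts[0])
            vals = [_parse_allele(t, line_no) for t in parts[1:]]
            cell = np.array(vals, dtype=np.int64).reshape(-1, 2)
            cell[np.any(cell == 0, axis=1)] = MISSING
            calls.append(cell)
    if not individuals:
        raise ParseError("no genotype rows")
    return GenotypeMatrix(individuals, loci, np.stack(calls))


def _write_genalex(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(l for loc in g.loci for l in (loc, loc)) + "\n")
        for i, ind in enumerate(g.individuals):
            toks = []
            for j in range(g.n_loci):
                a, b = g.calls[i, j]
                toks += ["0", "0"] if a == MISSING else [str(a), str(b)]
            fh.write(ind + "\t" + "\t".join(toks) + "\n")


_DIALECTS = {
    "tsv": (_read_tsv, _write_tsv),
    "structure_fmt": (_read_structure, _write_structure),
    "genalex_fmt": (_read_genalex, _write_genalex),
}


def read_genotype_table(path: str | Path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype panel file in one of the supported dialects.

    Dialects: ``tsv`` (cells ``a/b`` or ``.``), ``structure_fmt`` (two rows
    per individual, ``-9`` missing), ``genalex_fmt`` (two columns per locus,
    ``0`` missing).  Individual and locus order is preserved from the file.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    return _DIALECTS[dialect][0](Path(path))


def write_genotype_table(g: GenotypeMatrix, path: str | Path, dialect: str = "tsv") -> None:
    """Write a genotype panel; inverse of :func:`read_genotype_table`."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    _DIALECTS[dialect][1](g, Path(path))


def read_marker_map(path: str | Path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "scaffold": str})
    df = df.set_index("locus")
    df["linkage_group"] = df["linkage_group"].astype(int)
    df["cm"] = df["cm"].astype(float)
    df["bp"] = df["bp"].astype(float)
    return MarkerMap(df)


def write_marker_map(m: MarkerMap, path: str | Path) -> None:
    out = m.table.reset_index().rename(columns={"index": "locus"})
    out.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("id")
    return SampleMetadata(df)


def write_metadata(md: SampleMetadata, path: str | Path) -> None:
    md.table.reset_index().to_csv(path, sep="\t", index=False)


def _packaged(name: str):
    return importlib.resources.files("ssrpop.data").joinpath(name)


def load_packaged_marker_map() -> MarkerMap:
    """The 48-SSR peach marker map shipped with the package (8 linkage groups)."""
    with importlib.resources.as_file(_packaged("marker_map.tsv")) as p:
        return read_marker_map(p)


def load_packaged_locus_table() -> pd.DataFrame:
    """Published per-locus diversity values for the 48-SSR peach panel.

    Columns: n, Ao, Ae, Ho, He, F, PD, MAF, Gn, indexed by locus.  Used for
    arithmetic-consistency checks, not as a substitute for computation.
    """
    with importlib.resources.as_file(_packaged("locus_diversity_panel.tsv")) as p:
        return pd.read_csv(p, sep="\t").set_index("locus")


def load_packaged_ld_summary() -> pd.DataFrame:
    """Published per-subpopulation LD comparison counts for the peach panel."""
    with importlib.resources.as_file(_packaged("ld_summary_subpops.tsv")) as p:
        return pd.read_csv(p, sep="\t").set_index("subpopulation")


# ---------------------------------------------------------------------------
# Frequency computation and filtering
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencyTable:
    """Allele frequencies per locus over non-missing calls.

    Each allele copy counts once (a homozygote contributes two copies of one
    allele).  Missing cells are dropped per locus, so sample sizes vary by
    locus.  A locus with no non-missing call is an error.
    """
    freqs: dict[str, dict[int, float]] = {}
    n: dict[str, int] = {}
    for j, locus in enumerate(g.loci):
        col = g.calls[:, j, :]
        obs = col[col[:, 0] != MISSING]
        if obs.size == 0:
            raise GenodataError(f"locus {locus!r} has no non-missing calls")
        alleles, counts = np.unique(obs.ravel(), return_counts=True)
        total = counts.sum()
        freqs[locus] = {int(a): c / total for a, c in zip(alleles, counts)}
        n[locus] = len(obs)
    return AlleleFrequencyTable(freqs, n)


def recode_rare_alleles(g: GenotypeMatrix, maf_min: float) -> GenotypeMatrix:
    """Set to missing every cell carrying an allele rarer than ``maf_min``.

    Frequencies are those of the *input* matrix (a single pass, no iterative
    re-filtering).  Because a diploid cell cannot be half missing, the whole
    cell is blanked when either copy is a rare allele.
    """
    if not 0 <= maf_min < 1:
        raise ValueError(f"maf_min must be in [0, 1), got {maf_min}")
    if maf_min == 0:
        return GenotypeMatrix(g.individuals, g.loci, g.calls.copy())
    aft = allele_frequencies(g)
    calls = g.calls.copy()
    for j, locus in enumerate(g.loci):
        rare = {a for a, f in aft.freqs[locus].items() if f < maf_min}
        if not rare:
            continue
        col = calls[:, j, :]
        hit = np.isin(col, list(rare)).any(axis=1)
        col[hit] = MISSING
    return GenotypeMatrix(g.individuals, g.loci, calls)


def thin_markers(marker_map: MarkerMap, min_cm: float,
                 loci: Sequence[str] | None = None) -> list[str]:
    """Greedy left-to-right marker thinning at a minimum cM spacing.

    Within each linkage group, markers are scanned in increasing genetic
    position; a marker is kept iff it lies at least ``min_cm`` from the last
    kept marker.  Returns kept locus ids in map order.
    """
    df = marker_map.table
    if loci is not None:
        df = df.loc[[l for l in loci if l in df.index]]
    if df["cm"].isna().any():
        missing = df.index[df["cm"].isna()][0]
        raise GenodataError(f"locus {missing!r} has no genetic position")
    kept: list[str] = []
    for _, grp in df.groupby("linkage_group", sort=True):
        grp = grp.sort_values("cm", kind="stable")
        last = None
        for locus, row in grp.iterrows():
            if last is None or row["cm"] - last >= min_cm:
                kept.append(str(locus))
                last = float(row["cm"])
    return kept


def subset(g: GenotypeMatrix,
           individuals: Iterable[str] | None = None,
           loci: Iterable[str] | None = None) -> GenotypeMatrix:
    """Order-preserving restriction to the requested individuals and/or loci."""
    if individuals is None:
        rows = np.arange(g.n_individuals)
        ind_ids = g.individuals
    else:
        ind_ids = list(individuals)
        pos = {s: i for i, s in enumerate(g.individuals)}
        try:
            rows = np.array([pos[s] for s in ind_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown individual: {e.args[0]!r}") from None
    if loci is None:
        cols = np.arange(g.n_loci)
        loc_ids = g.loci
    else:
        loc_ids = list(loci)
        pos = {s: i for i, s in enumerate(g.loci)}
        try:
            cols = np.array([pos[s] for s in loc_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown locus: {e.args[0]!r}") from None
    return GenotypeMatrix(ind_ids, loc_ids, g.calls[np.ix_(rows, cols)])
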