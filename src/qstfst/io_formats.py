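"""Readers and writers for the three study inputs.

The pipeline consumes (a) multi-allelic genotypes with population labels in
the classic GenePop dialect, (b) a tidy phenotype table from a randomized
block common garden (individual, subspecies, population, family, block and
one column per trait), and (c) per-population metadata (coordinates,
altitude, subspecies).  Everything is held in plain dataclasses wrapping
numpy arrays / pandas frames so downstream estimators can operate on codes
rather than strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel allele code for a missing call (GenePop all-zeros convention)
MISSING = 0

REQUIRED_PHENOTYPE_COLUMNS = ["individual", "subspecies", "population", "family", "block"]
METADATA_COLUMNS = ["population", "subspecies", "latitude", "longitude", "altitude"]


class GenepopParseError(ValueError):
    """Raised when a GenePop file violates the dialect."""


class SchemaError(ValueError):
    """Raised when a delimited file lacks required columns or valid values."""


@dataclass
class GenotypeTable:
    """Diploid multi-allelic genotypes for individuals grouped in populations.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` holding integer allele
    codes; alleles are opaque labels (their numeric value carries no meaning
    for any estimator here) and ``0`` marks a missing call.
    """

    individuals: list[str]
    populations: np.ndarray  # population label per individual, dtype object/str
    loci: list[str]
    calls: np.ndarray  # (n, L, 2) int

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls shape {self.calls.shape} != {(n, L, 2)}")
        if len(self.populations) != n:
            raise ValueError("one population label per individual required")

    @property
    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_of(self, individual: str) -> str:
        return self.populations[self.individuals.index(individual)]

    def subset(self, populations) -> "GenotypeTable":
        keep = np.isin(self.populations, list(populations))
        return GenotypeTable(
            [i for i, k in zip(self.individuals, keep) if k],
            self.populations[keep],
            list(self.loci),
            self.calls[keep],
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeTable)
            and self.individuals == other.individuals
            and list(self.populations) == list(other.populations)
            and self.loci == other.loci
            and sorted_calls_equal(self.calls, other.calls)
        )


def sorted_calls_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Compare diploid calls as unordered pairs."""
    return bool(np.array_equal(np.sort(a, axis=-1), np.sort(b, axis=-1)))


@dataclass
class PhenotypeTable:
    """Tidy per-plant phenotypes with the common-garden design factors."""

    data: pd.DataFrame
    traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in REQUIRED_PHENOTYPE_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"phenotype table lacks required column {col!r}")
        if not self.traits:
            self.traits = [c for c in self.data.columns if c not in REQUIRED_PHENOTYPE_COLUMNS]
        for col in REQUIRED_PHENOTYPE_COLUMNS:
            self.data[col] = self.data[col].astype(str)
        for t in self.traits:
            vals = self.data[t].to_numpy(dtype=float)
            if np.any(np.isinf(vals)):
                raise ValueError(f"non-finite value in trait {t!r}")

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.data["population"]))

    def subset(self, populations) -> "PhenotypeTable":
        mask = self.data["population"].isin(list(populations))
        return PhenotypeTable(self.data.loc[mask].reset_index(drop=True), list(self.traits))

    def trait_values(self, trait: str) -> pd.DataFrame:
        """Rows with a non-missing value for one trait (listwise deletion)."""
        if trait not in self.traits:
            raise KeyError(trait)
        sub = self.data[REQUIRED_PHENOTYPE_COLUMNS + [trait]].dropna(subset=[trait])
        return sub.reset_index(drop=True)


@dataclass
class PopulationMetadata:
    """Per-population coordinates (decimal degrees), altitude (m), subspecies."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in METADATA_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"metadata lacks required column {col!r}")
        if self.data["population"].duplicated().any():
            dup = self.data["population"][self.data["population"].duplicated()].iloc[0]
            raise ValueError(f"duplicate population label {dup!r} in metadata")
        lat = self.data["latitude"].to_numpy(dtype=float)
        lon = self.data["longitude"].to_numpy(dtype=float)
        alt = self.data["altitude"].to_numpy(dtype=float)
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitude out of range [-90, 90]")
        if np.any(np.abs(lon) > 180):
            raise ValueError("longitude out of range [-180, 180]")
        if np.any(alt < 0):
            raise ValueError("altitude must be non-negative")
        self.data = self.data.reset_index(drop=True)

    @property
    def populations(self) -> list[str]:
        return list(self.data["population"])

    def record(self, population: str) -> pd.Series:
        rows = self.data[self.data["population"] == population]
        if rows.empty:
            raise KeyError(population)
        return rows.iloc[0]

    def coordinates(self, populations=None) -> np.ndarray:
        pops = list(populations) if populations is not None else self.populations
        idx = [self.populations.index(p) for p in pops]
        return self.data.loc[idx, ["latitude", "longitude"]].to_numpy(dtype=float)

    def altitudes(self, populations=None) -> np.ndarray:
        pops = list(populations) if populations is not None else self.populations
        idx = [self.populations.index(p) for p in pops]
        return self.data.loc[idx, "altitude"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path) -> GenotypeTable:
    """Parse a GenePop file into a :class:`GenotypeTable`.

    Dialect: a title line; locus names one per line or comma-separated;
    ``POP`` separators; individual lines ``id , a1a2 a1a2 ...`` with 2- or
    3-digit allele codes (width inferred per file and required consistent);
    an all-zeros code is a missing call.  Populations are named by the
    common ``_``-prefix of the section's individual ids when one exists,
    else ``pop1..popN``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty file")

    # locus names: everything between the title line and the first POP
    first_pop = next((i for i, l in enumerate(lines) if _POP_RE.match(l)), None)
    if first_pop is None:
        raise GenepopParseError("no POP section found")
    loci: list[str] = []
    for line in lines[1:first_pop]:
        loci.extend(tok.strip() for tok in line.split(",") if tok.strip())
    if not loci:
        raise GenepopParseError("no locus names before first POP")

    individuals: list[str] = []
    pop_index: list[int] = []
    raw_calls: list[list[str]] = []
    section = -1
    for lineno, line in enumerate(lines[first_pop:], start=first_pop + 1):
        if _POP_RE.match(line):
            section += 1
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise GenepopParseError(f"line {lineno}: expected 'id , genotypes ...'")
        ind_id, _, geno = line.partition(",")
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"line {lineno}: {len(tokens)} genotype fields for {len(loci)} loci"
            )
        individuals.append(ind_id.strip())
        pop_index.append(section)
        raw_calls.append(tokens)

    if section < 0 or not individuals:
        raise GenepopParseError("no individuals found")

    widths = {len(tok) for row in raw_calls for tok in row}
    if not widths <= {4, 6}:
        bad = sorted(widths - {4, 6})
        raise GenepopParseError(f"genotype field width(s) {bad} not in (4, 6)")
    if len(widths) != 1:
        raise GenepopParseError("mixed 2- and 3-digit allele codes in one file")
    half = widths.pop() // 2

    n, L = len(individuals), len(loci)
    calls = np.zeros((n, L, 2), dtype=np.int64)
    for i, row in enumerate(raw_calls):
        for j, tok in enumerate(row):
            if not tok.isdigit():
                raise GenepopParseError(f"non-numeric genotype field {tok!r}")
            calls[i, j] = (int(tok[:half]), int(tok[half:]))

    pop_index_arr = np.asarray(pop_index)
    names = _section_names(individuals, pop_index_arr, section + 1)
    populations = np.asarray([names[s] for s in pop_index], dtype=object)
    return GenotypeTable(individuals, populations, loci, calls)


def _section_names(individuals, pop_index, n_sections) -> list[str]:
    names = []
    for s in range(n_sections):
        ids = [i for i, p in zip(individuals, pop_index) if p == s]
        prefixes = {i.split("_")[0] for i in ids}
        if len(prefixes) == 1 and "_" in ids[0]:
            names.append(prefixes.pop())
        else:
            names.append(f"pop{s + 1}")
    return names


def write_genepop(g: GenotypeTable, path, title: str = "qstfst genotypes") -> None:
    """Write a GenotypeTable in GenePop dialect (3-digit allele codes)."""
    if (g.calls >= 1000).any() or (g.calls < 0).any():
        raise ValueError("allele codes must be in [0, 999] for 3-digit GenePop output")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(title + "\n")
        for locus in g.loci:
            fh.write(locus + "\n")
        for pop in g.population_labels:
            fh.write("POP\n")
            for i, ind in enumerate(g.individuals):
                if g.populations[i] != pop:
                    continue
                fields = ["%03d%03d" % tuple(pair) for pair in g.calls[i]]
                fh.write(f"{ind} , " + " ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    counts = {d: header.count(d) for d in (",", ";", "\t")}
    return max(counts, key=counts.get)


def read_phenotype_csv(path) -> PhenotypeTable:
    """Read a tidy phenotype table; delimiter auto-detected (, ; tab)."""
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in REQUIRED_PHENOTYPE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"phenotype file lacks required column {col!r}")
    traits = [c for c in df.columns if c not in REQUIRED_PHENOTYPE_COLUMNS]
    out = df[REQUIRED_PHENOTYPE_COLUMNS].copy()
    for t in traits:
        vals = []
        for idx, cell in enumerate(df[t]):
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError as exc:
                raise ValueError(f"non-numeric value {cell!r} for trait {t!r} in row {idx}") from exc
        out[t] = vals
    return PhenotypeTable(out, traits)


def write_phenotype_csv(p: PhenotypeTable, path) -> None:
    cols = REQUIRED_PHENOTYPE_COLUMNS + list(p.traits)
    p.data[cols].to_csv(path, index=False, encoding="utf-8")


def read_population_metadata(path) -> PopulationMetadata:
    """Read per-population metadata; delimiter auto-detected (, ; tab)."""
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"metadata file lacks required column {col!r}")
    df["population"] = df["population"].astype(str)
    df["subspecies"] = df["subspecies"].astype(str)
    return PopulationMetadata(df[METADATA_COLUMNS].copy())


def write_population_metadata(m: PopulationMetadata, path) -> None:
    m.data[METADATA_COLUMNS].to_csv(path, index=False, encoding="utf-8")
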