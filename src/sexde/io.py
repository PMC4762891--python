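"""Readers/writers for expression matrices, sample metadata, GMT gene sets and ID maps.

All formats are plain UTF-8, tab-delimited text with Unix newlines.  Missing
covariate cells are encoded as the literal ``NA``.  Readers enforce the type
invariants (unique identifiers, finite values, required columns) and raise
:class:`~sexde.exceptions.FormatError` naming the offending row/column rather
than silently repairing the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from sexde.exceptions import FormatError, ParameterError

SEXES = ("male", "female")

#: background categories recognized in the GMT description column
KNOWN_BACKGROUND_CATEGORIES = ("protein_coding", "orthologue_1to1")
SOURCE_PUBLICATION_PREFIX = "source_publication:"
DEFAULT_BACKGROUND_CATEGORY = "protein_coding"

#: sample-metadata columns; sex and subject may never be missing
REQUIRED_SAMPLE_COLUMNS = ("sex", "subject")
OPTIONAL_SAMPLE_COLUMNS = ("region", "lobe", "age", "RIN", "PMI", "pH")


def _is_known_category(tag: str) -> bool:
    return tag in KNOWN_BACKGROUND_CATEGORIES or tag.startswith(SOURCE_PUBLICATION_PREFIX)


@dataclass
class ExpressionMatrix:
    """Dense genes x samples matrix of log2-scale expression values.

    ``data`` is indexed by gene ID with sample IDs as columns.  Values are
    finite floats; gene and sample identifiers are unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene IDs: {dup[:5]}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dup[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            gi, si = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite expression value at gene {idx[gi]!r}, sample {cols[si]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)])


@dataclass
class SampleTable:
    """Per-sample metadata: sex, subject and quality covariates.

    ``data`` is indexed by sample ID.  ``sex`` (male/female) and ``subject``
    are mandatory and never missing; region, lobe, age, RIN, PMI and pH are
    optional and may contain NA.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs in sample table: {dup[:5]}")
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in self.data.columns:
                raise FormatError(f"sample table missing required column {col!r}")
            if self.data[col].isna().any():
                bad = self.data.index[self.data[col].isna()][0]
                raise FormatError(f"missing {col!r} for sample {bad!r}")
        bad_sex = set(self.data["sex"].unique()) - set(SEXES)
        if bad_sex:
            raise FormatError(f"sex must be one of {SEXES}; found {sorted(bad_sex)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sex(self) -> pd.Series:
        return self.data["sex"]

    @property
    def subject(self) -> pd.Series:
        return self.data["subject"]

    def subset(self, samples: Sequence[str]) -> "SampleTable":
        return SampleTable(self.data.loc[list(samples)])

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        missing = set(matrix.sample_ids) - set(self.sample_ids)
        if missing:
            raise ParameterError(
                f"sample table does not cover matrix columns: {sorted(missing)[:5]}"
            )


@dataclass
class GeneSet:
    genes: list[str]
    background_category: str = DEFAULT_BACKGROUND_CATEGORY


@dataclass
class GeneSetCollection:
    """Named gene sets, each tagged with a background category.

    ``backgrounds`` maps category names to gene universes; when non-empty,
    every set's category must resolve to a non-empty background list.
    """

    sets: dict[str, GeneSet] = field(default_factory=dict)
    backgrounds: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.backgrounds:
            self.validate_backgrounds()

    def validate_backgrounds(self) -> None:
        for name, gs in self.sets.items():
            cat = gs.background_category
            if cat not in self.backgrounds:
                raise ParameterError(
                    f"set {name!r} references unknown background category {cat!r}"
                )
            if not self.backgrounds[cat]:
                raise ParameterError(f"background category {cat!r} is empty")

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    def genes_of(self, name: str) -> list[str]:
        return self.sets[name].genes


@dataclass
class IdMap:
    """One-to-one gene-ID mapping after collision resolution.

    Many-to-one collisions (several sources mapping to one target) are
    resolved by dropping all colliding sources, which are reported; this keeps
    every surviving comparison unambiguous.
    """

    mapping: dict[str, str]
    dropped_collisions: list[str] = field(default_factory=list)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "IdMap":
        raw: dict[str, str] = {}
        for src, tgt in pairs:
            if src in raw and raw[src] != tgt:
                raise FormatError(f"source ID {src!r} maps to multiple targets")
            raw[src] = tgt
        by_target: dict[str, list[str]] = {}
        for src, tgt in raw.items():
            by_target.setdefault(tgt, []).append(src)
        dropped = sorted(
            src for srcs in by_target.values() if len(srcs) > 1 for src in srcs
        )
        mapping = {s: t for s, t in raw.items() if s not in set(dropped)}
        return cls(mapping=mapping, dropped_collisions=dropped)


# ---------------------------------------------------------------------------
# expression matrix I/O


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (header of sample IDs, first column gene IDs)."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed TSV: {exc}") from exc
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene IDs: {dup[:5]}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample IDs: {dup[:5]}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: unparseable number {raw.iat[gi, si]!r} "
            f"at gene {raw.index[gi]!r}, sample {raw.columns[si]!r}"
        )
    if numeric.isna().to_numpy().any():
        gi, si = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at gene {raw.index[gi]!r}, sample {raw.columns[si]!r}"
        )
    numeric.index.name = raw.index.name or "gene"
    return ExpressionMatrix(numeric)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = df.index.name or "gene"
    df.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# sample table I/O


def read_samples(path: str | Path) -> SampleTable:
    """Read per-sample metadata TSV; ``NA`` encodes a missing covariate."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, na_values=["NA"], keep_default_na=False
    )
    for col in ("age", "RIN", "PMI", "pH"):
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{path}: non-numeric {col}: {exc}") from exc
    return SampleTable(df)


def write_samples(samples: SampleTable, path: str | Path) -> None:
    df = samples.data.copy()
    df.index.name = df.index.name or "sample"
    df.to_csv(path, sep="\t", na_rep="NA", lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB gene1 TAB gene2 ...).

    The description column is overloaded to carry the background category; an
    unrecognized description falls back to the default category.  Gene lists
    are deduplicated preserving order.
    """
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            category = desc if _is_known_category(desc) else DEFAULT_BACKGROUND_CATEGORY
            sets[name] = GeneSet(genes=genes, background_category=category)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, gs in collection.sets.items():
            fh.write("\t".join([name, gs.background_category, *gs.genes]) + "\n")


def read_backgrounds(directory: str | Path) -> dict[str, list[str]]:
    """Read background gene lists from ``<category>.txt`` files (one ID per line)."""
    directory = Path(directory)
    backgrounds: dict[str, list[str]] = {}
    for f in sorted(directory.glob("*.txt")):
        genes = [ln.strip() for ln in f.read_text(encoding="utf-8").splitlines() if ln.strip()]
        backgrounds[f.stem] = list(dict.fromkeys(genes))
    return backgrounds


def write_backgrounds(backgrounds: Mapping[str, Sequence[str]], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cat, genes in backgrounds.items():
        (directory / f"{cat}.txt").write_text(
            "".join(g + "\n" for g in genes), encoding="utf-8"
        )


# ---------------------------------------------------------------------------
# ID mapping


def read_id_map(path: str | Path) -> IdMap:
    """Read a two-column source/target TSV into an :class:`IdMap`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: ID map needs two columns (source, target)")
    pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return IdMap.from_pairs(pairs)


@dataclass
class MapReport:
    unmapped: list[str]
    collisions: list[str]

    @property
    def n_dropped(self) -> int:
        return len(self.unmapped) + len(self.collisions)


def map_ids(collection: GeneSetCollection, idmap: IdMap) -> tuple[GeneSetCollection, MapReport]:
    """Translate every gene ID in a collection through a one-to-one map.

    Genes with no mapping are dropped from sets and reported; sources dropped
    by the map's collision resolution are reported separately.
    """
    unmapped: set[str] = set()
    collided: set[str] = set()
    collision_set = set(idmap.dropped_collisions)

    def translate(genes: Sequence[str]) -> list[str]:
        out: list[str] = []
        for g in genes:
            if g in idmap.mapping:
                out.append(idmap.mapping[g])
            elif g in collision_set:
                collided.add(g)
            else:
                unmapped.add(g)
        return list(dict.fromkeys(out))

    new_sets = {
        name: GeneSet(genes=translate(gs.genes), background_category=gs.background_category)
        for name, gs in collection.sets.items()
    }
    new_backgrounds = {cat: translate(genes) for cat, genes in collection.backgrounds.items()}
    mapped = GeneSetCollection(sets=new_sets, backgrounds=new_backgrounds)
    report = MapReport(unmapped=sorted(unmapped), collisions=sorted(collided))
    return mapped, report


# ---------------------------------------------------------------------------
# truth tables (simulation ground truth)


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"sets": str}, keep_default_na=False, na_values=[""])
    df["true_log2fd"] = pd.to_numeric(df["true_log2fd"])
    df["sets"] = df["sets"].fillna("")
    return df


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    df = truth.copy()
    df.index.name = df.index.name or "gene"
    df.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")
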