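"""Readers and writers for the text formats the pipeline touches.

Expression matrices come in as GCT v1.2 or plain TSV, phenotype labels as
CLS or two-column TSV, gene networks as GMT (the MSigDB dialect), and gene
synonym tables as two-column TSV.  Everything is assembled into an
:class:`ExpressionStudy`, the validated genes x samples container that the
scoring code consumes.  All analysis is rank-based, so no normalisation is
performed (or needed) on the way in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "GeneNetwork",
    "NetworkCollection",
    "read_gmt",
    "write_gmt",
    "read_synonyms",
    "attach_networks",
    "read_expression",
    "write_expression_tsv",
    "write_expression_gct",
    "read_labels",
    "write_cls",
    "write_table",
]


class FormatError(ValueError):
    """A file does not satisfy its declared format contract."""


@dataclass(frozen=True)
class ExpressionStudy:
    """A genes x samples expression matrix with optional phenotype labels.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene symbol, one column per sample, all
        entries finite floats.  Units are arbitrary: only within-sample
        orderings are ever used.
    labels
        Series mapping sample id to phenotype label, aligned to
        ``values.columns``; ``None`` for an unlabeled study.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            dupes = vals.index[vals.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if vals.columns.has_duplicates:
            dupes = vals.columns[vals.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        if self.labels is not None:
            if list(self.labels.index) != list(vals.columns):
                raise ValueError("labels are not aligned to sample columns")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def phenotypes(self) -> list[str]:
        if self.labels is None:
            return []
        # preserve first-appearance order
        return list(dict.fromkeys(self.labels))

    def with_labels(self, labels: pd.Series | Sequence[str]) -> "ExpressionStudy":
        """Attach phenotype labels, realigning by sample id when indexed.

        A Series is matched by sample id (order-insensitive); a plain
        sequence is taken positionally and must have one label per sample.
        """
        if isinstance(labels, pd.Series):
            missing = [s for s in self.sample_ids if s not in labels.index]
            if missing:
                raise ValueError(f"samples without a label: {missing[:5]}")
            aligned = labels.reindex(self.sample_ids)
        else:
            labels = list(labels)
            if len(labels) != self.n_samples:
                raise ValueError(
                    f"{len(labels)} labels for {self.n_samples} samples"
                )
            aligned = pd.Series(labels, index=self.sample_ids)
        aligned = aligned.astype(str)
        aligned.name = "phenotype"
        return replace(self, labels=aligned)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionStudy":
        vals = self.values.loc[:, list(sample_ids)]
        labels = None if self.labels is None else self.labels.loc[list(sample_ids)]
        return ExpressionStudy(vals, labels)

    def require_min_class_size(self, minimum: int = 2) -> None:
        """Raise unless every phenotype has at least ``minimum`` samples."""
        if self.labels is None:
            raise ValueError("study has no phenotype labels")
        counts = self.labels.value_counts()
        small = counts[counts < minimum]
        if len(small):
            raise ValueError(
                "phenotypes with fewer than "
                f"{minimum} samples: {dict(small)}"
            )


@dataclass(frozen=True)
class GeneNetwork:
    """A named gene list; after :func:`attach_networks`, restricted to
    genes measured in a study.

    ``coverage`` is the fraction of the GMT-declared genes found in the
    study (after synonym remapping); ``raw_size`` the declared gene count.
    """

    name: str
    genes: tuple[str, ...]
    coverage: float | None = None
    raw_size: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"network {self.name!r} has duplicate genes")

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def n_pairs(self) -> int:
        g = len(self.genes)
        return g * (g - 1) // 2


@dataclass
class NetworkCollection:
    """An ordered collection of gene networks with unique names."""

    networks: list[GeneNetwork] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [n.name for n in self.networks]
        if len(set(names)) != len(names):
            seen: set[str] = set()
            dupes = [n for n in names if n in seen or seen.add(n)]
            raise ValueError(f"duplicate network names: {sorted(set(dupes))}")

    def __iter__(self):
        return iter(self.networks)

    def __len__(self) -> int:
        return len(self.networks)

    def __getitem__(self, name: str) -> GeneNetwork:
        for net in self.networks:
            if net.name == name:
                return net
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.networks]


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> NetworkCollection:
    """Read a GMT file: one network per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are dropped keeping the first occurrence;
    empty gene tokens are ignored.  Lines with fewer than three fields and
    duplicate network names are errors.
    """
    path = Path(path)
    networks: list[GeneNetwork] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected name, description and at least one gene"
                )
            name = fields[0].strip()
            genes = [g.strip() for g in fields[2:]]
            genes = list(dict.fromkeys(g for g in genes if g))
            networks.append(GeneNetwork(name=name, genes=tuple(genes)))
    return NetworkCollection(networks)


def write_gmt(collection: NetworkCollection | Iterable[GeneNetwork], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for net in collection:
            fh.write("\t".join([net.name, "na", *net.genes]) + "\n")


# ---------------------------------------------------------------------------
# Gene synonyms


def read_synonyms(path: str | Path) -> dict[str, str]:
    """Read a two-column alias -> canonical-symbol TSV (header optional).

    The returned mapping is normalised so that chasing an alias lands on a
    canonical symbol in one step (idempotent on canonical symbols).
    """
    path = Path(path)
    raw: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: synonym line needs 2 columns"
                )
            alias, canonical = fields[0].strip(), fields[1].strip()
            if lineno == 1 and alias.lower() in {"alias", "synonym"}:
                continue
            raw[alias] = canonical
    # collapse alias chains so the map is one-step
    resolved = {}
    for alias, canonical in raw.items():
        seen = {alias}
        while canonical in raw and canonical not in seen:
            seen.add(canonical)
            canonical = raw[canonical]
        resolved[alias] = canonical
    return resolved


def _casefold_index(symbols: Iterable[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for s in symbols:
        key = s.strip().casefold()
        out.setdefault(key, s)
    return out


def attach_networks(
    study: ExpressionStudy,
    collection: NetworkCollection,
    synonym_map: Mapping[str, str] | None = None,
    min_genes: int = 2,
) -> list[GeneNetwork]:
    """Restrict raw gene sets to the genes measured in ``study``.

    Gene matching is case-insensitive after whitespace stripping.  Genes
    absent from the study are remapped through ``synonym_map`` (if given)
    and kept only if the canonical symbol is measured.  Networks retaining
    fewer than ``min_genes`` genes are excluded and logged.  The surviving
    gene list is sorted so downstream pair enumeration is reproducible
    regardless of GMT line-internal order.
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2: all statistics need a pair")
    study_index = _casefold_index(study.gene_ids)
    syn_index = {}
    if synonym_map:
        syn_index = {a.strip().casefold(): c for a, c in synonym_map.items()}

    attached: list[GeneNetwork] = []
    for net in collection:
        matched: list[str] = []
        for gene in net.genes:
            key = gene.strip().casefold()
            if key not in study_index and key in syn_index:
                key = syn_index[key].strip().casefold()
            if key in study_index:
                matched.append(study_index[key])
        matched = sorted(dict.fromkeys(matched))
        coverage = len(matched) / len(net.genes) if net.genes else 0.0
        if len(matched) < min_genes:
            logger.info(
                "excluding network %s: %d of %d genes measured (min_genes=%d)",
                net.name, len(matched), len(net.genes), min_genes,
            )
            continue
        attached.append(
            GeneNetwork(
                name=net.name,
                genes=tuple(matched),
                coverage=coverage,
                raw_size=len(net.genes),
            )
        )
    if not attached:
        raise ValueError("no usable networks: empty intersection with study genes")
    return attached


# ---------------------------------------------------------------------------
# Expression matrices


def _collapse_duplicates(df: pd.DataFrame, how: str) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    if how == "first":
        return df[~df.index.duplicated(keep="first")]
    if how == "mean":
        return df.groupby(level=0, sort=False).mean()
    if how == "max_mean":
        means = df.mean(axis=1).to_numpy()
        order = np.arange(len(df))
        pick = (
            pd.DataFrame({"mean": means, "order": order}, index=df.index)
            .groupby(level=0, sort=False)["mean"]
            .idxmax()
        )
        # idxmax on a duplicated index returns labels; recompute positions
        keep_positions = []
        for symbol in pick.index:
            positions = np.flatnonzero(df.index == symbol)
            best = positions[np.argmax(means[positions])]
            keep_positions.append(best)
        return df.iloc[sorted(keep_positions)]
    raise ValueError(f"unknown collapse rule {how!r}")


def _check_header_duplicates(header_line: str, path: Path, skip: int) -> None:
    # pandas silently mangles duplicate column names, so inspect the raw header
    samples = header_line.rstrip("\n").split("\t")[skip:]
    seen: set[str] = set()
    dupes = [s for s in samples if s in seen or seen.add(s)]
    if dupes:
        raise FormatError(f"{path}: duplicate sample ids {sorted(set(dupes))[:5]}")


def _validate_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    n_missing = int(numeric.isna().any(axis=1).sum())
    if n_missing:
        logger.info("dropping %d gene rows with missing values", n_missing)
        numeric = numeric.dropna(axis=0)
    return numeric.astype(float)


def read_expression(
    path: str | Path,
    format: str | None = None,
    collapse: str = "max_mean",
) -> ExpressionStudy:
    """Read a GCT v1.2 or TSV expression matrix into an unlabeled study.

    Rows sharing a gene symbol are collapsed per ``collapse``:
    ``max_mean`` keeps the row with the highest mean expression, ``mean``
    averages element-wise, ``first`` keeps the first occurrence.  Rows with
    any missing value are dropped (and logged) — rank statistics need
    complete profiles.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        with path.open() as fh:
            version = fh.readline().strip()
            if version not in {"#1.2", "1.2"}:
                raise FormatError(f"{path}: not a GCT v1.2 file ({version!r})")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError(f"{path}: malformed GCT dimension line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            header = fh.readline()
            _check_header_duplicates(header, path, skip=2)
            df = pd.read_csv(
                fh, sep="\t", index_col=0, dtype=str, header=None,
                names=[h.strip() for h in header.rstrip("\n").split("\t")],
            )
        df = df.drop(columns=df.columns[0])  # Description column
        if df.shape != (n_genes, n_samples):
            raise FormatError(
                f"{path}: GCT declares {n_genes}x{n_samples} but body is "
                f"{df.shape[0]}x{df.shape[1]}"
            )
    elif format == "tsv":
        with path.open() as fh:
            header = fh.readline()
            while header.startswith("#"):
                header = fh.readline()
            _check_header_duplicates(header, path, skip=1)
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    else:
        raise ValueError(f"unknown expression format {format!r}")
    df.index = df.index.astype(str).str.strip()
    df = _validate_numeric(df, path)
    df = _collapse_duplicates(df, collapse)
    return ExpressionStudy(df)


def write_expression_tsv(study: ExpressionStudy, path: str | Path) -> None:
    df = study.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_expression_gct(study: ExpressionStudy, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{study.values.shape[0]}\t{study.values.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(study.sample_ids) + "\n")
        for gene, row in study.values.iterrows():
            vals = "\t".join(f"{v:.6g}" for v in row)
            fh.write(f"{gene}\tna\t{vals}\n")


# ---------------------------------------------------------------------------
# Phenotype labels


def read_labels(path: str | Path, format: str | None = None) -> pd.Series | list[str]:
    """Read phenotype labels from CLS (positional) or TSV (by sample id).

    CLS returns a plain list aligned to sample order; TSV returns a Series
    indexed by sample id, realigned by :meth:`ExpressionStudy.with_labels`.
    """
    path = Path(path)
    if format is None:
        format = "cls" if path.suffix.lower() == ".cls" else "tsv"
    if format == "cls":
        lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        if len(lines) < 3:
            raise FormatError(f"{path}: CLS needs 3 non-empty lines")
        header = lines[0].split()
        n_samples, n_classes = int(header[0]), int(header[1])
        class_names = lines[1].lstrip("#").split()
        if len(class_names) != n_classes:
            raise FormatError(
                f"{path}: CLS declares {n_classes} classes but names "
                f"{len(class_names)}"
            )
        tokens = lines[2].split()
        if len(tokens) != n_samples:
            raise FormatError(
                f"{path}: CLS declares {n_samples} samples but labels "
                f"{len(tokens)}"
            )
        if all(t.isdigit() for t in tokens) and set(class_names) != set(tokens):
            labels = [class_names[int(t)] for t in tokens]
        else:
            labels = tokens
        unknown = sorted(set(labels) - set(class_names))
        if unknown:
            raise FormatError(f"{path}: labels not among class names: {unknown}")
        return labels
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        if df.shape[1] < 2:
            raise FormatError(f"{path}: label TSV needs (sample_id, label) columns")
        series = pd.Series(
            df.iloc[:, 1].str.strip().to_numpy(),
            index=df.iloc[:, 0].str.strip(),
            name="phenotype",
        )
        if series.index.has_duplicates:
            raise FormatError(f"{path}: duplicate sample ids in label file")
        return series
    raise ValueError(f"unknown label format {format!r}")


def write_cls(labels: Sequence[str], path: str | Path) -> None:
    classes = list(dict.fromkeys(labels))
    with Path(path).open("w") as fh:
        fh.write(f"{len(labels)} {len(classes)} 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        fh.write(" ".join(str(cls) for cls in labels) + "\n")


# ---------------------------------------------------------------------------
# Result tables


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    header_comments: Sequence[str] = (),
    index: bool = False,
) -> None:
    """Write a result table as TSV with optional ``#`` header comments.

    Floats are written with 6 significant digits.
    """
    with Path(path).open("w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", float_format="%.6g", index=index)
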