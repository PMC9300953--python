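"""Readers and writers for every external table the pipeline touches.

All formats are tab-delimited text.  Readers validate eagerly and raise
:class:`~sighub.errors.FormatError` naming the offending line; writers are
exact inverses on valid data (full-precision float round trip via shortest
repr).  Gene symbols are case-sensitive and never remapped — alias
harmonization is the caller's job.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .synthetic import CATEGORY_VOCABULARY, MUTATION_STATUSES

__all__ = [
    "read_expression", "write_expression",
    "read_clinical", "write_clinical",
    "read_gene_sets", "write_gene_sets",
    "read_annotation", "write_annotation",
    "read_kinase_substrates", "write_kinase_substrates",
    "read_mutations", "write_mutations",
    "read_dependencies", "write_dependencies",
    "check_sample_overlap", "log2_transform",
]

PERTURBATIONS = ("crispr", "rnai", "compound")


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples matrix (first column gene symbols).

    Rejects duplicate gene symbols or sample IDs, negative, non-finite or
    missing values, and ragged rows.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:          # pandas parser errors carry line info
        raise FormatError(f"{path}: {exc}") from exc
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicated sample ID {dup!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        line = int(np.flatnonzero(df.index == dup)[1]) + 2
        raise FormatError(f"{path}, line {line}: duplicated gene symbol {dup!r}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    bad = ~np.isfinite(values.to_numpy()) | (values.to_numpy() < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.any(axis=1))[0])
        raise FormatError(
            f"{path}, line {row + 2}: negative, missing or non-finite value "
            f"in gene {values.index[row]!r}")
    values.index.name = "gene"
    return values


def write_expression(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


_STATUS_TOKENS = {
    "1:DECEASED": 1, "0:LIVING": 0, "DECEASED": 1, "LIVING": 0,
    "1": 1, "0": 0,
}


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical table: sample_id, os_months, os_event.

    The event column accepts cBioPortal-style dialects (``1:DECEASED`` /
    ``0:LIVING``) as well as bare 0/1.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for required in ("sample_id", "os_months", "os_event"):
        if required not in cols:
            raise FormatError(f"{path}: missing column {required!r}")
    out = pd.DataFrame()
    out["sample_id"] = df[cols["sample_id"]]
    if out["sample_id"].duplicated().any():
        dup = out["sample_id"][out["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicated sample ID {dup!r}")
    try:
        months = df[cols["os_months"]].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric os_months ({exc})") from exc
    if (months < 0).any() or not np.isfinite(months).all():
        row = int(np.flatnonzero((months < 0) | ~np.isfinite(months))[0])
        raise FormatError(f"{path}, line {row + 2}: invalid survival time "
                          f"{months.iloc[row]!r}")
    out["os_months"] = months
    events = []
    for i, tok in enumerate(df[cols["os_event"]].astype(str).str.strip()):
        if tok.upper() not in _STATUS_TOKENS:
            raise FormatError(f"{path}, line {i + 2}: unknown status token "
                              f"{tok!r}")
        events.append(_STATUS_TOKENS[tok.upper()])
    out["os_event"] = events
    return out


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical[["sample_id", "os_months", "os_event"]].to_csv(
        path, sep="\t", index=False)


def read_gene_sets(path) -> dict:
    """Read a GMT file: name, description, genes.  Order-preserving;
    duplicate genes within a set are counted once."""
    sets: dict[str, list] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}, line {ln}: GMT line needs at "
                                  f"least 3 tab-separated fields")
            name = fields[0]
            seen: dict[str, None] = {}
            for g in fields[2:]:
                if g:
                    seen.setdefault(g, None)
            sets[name] = list(seen)
    return sets


def write_gene_sets(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_annotation(path, vocabulary=CATEGORY_VOCABULARY) -> dict:
    """Read gene -> ``;``-separated category labels; labels must come from
    the controlled vocabulary."""
    anno: dict[str, frozenset] = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for required in ("gene", "categories"):
        if required not in cols:
            raise FormatError(f"{path}: missing column {required!r}")
    for i, (gene, cats) in enumerate(
            zip(df[cols["gene"]], df[cols["categories"]])):
        if gene in anno:
            raise FormatError(f"{path}, line {i + 2}: duplicated gene {gene!r}")
        labels = frozenset(c for c in str(cats).split(";") if c)
        bad = labels - set(vocabulary)
        if bad:
            raise FormatError(f"{path}, line {i + 2}: unknown category "
                              f"{sorted(bad)[0]!r}")
        anno[gene] = labels
    return anno


def write_annotation(annotation: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcategories\n")
        for gene in annotation:
            fh.write(f"{gene}\t{';'.join(sorted(annotation[gene]))}\n")


def read_kinase_substrates(path) -> dict:
    """Read kinase -> substrate pairs (one per line) into a mapping of sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for required in ("kinase", "substrate"):
        if required not in cols:
            raise FormatError(f"{path}: missing column {required!r}")
    ks: dict[str, set] = {}
    for kin, sub in zip(df[cols["kinase"]], df[cols["substrate"]]):
        ks.setdefault(kin, set()).add(sub)
    return ks


def write_kinase_substrates(ks_map: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("kinase\tsubstrate\n")
        for kin in sorted(ks_map):
            for sub in sorted(ks_map[kin]):
                fh.write(f"{kin}\t{sub}\n")


def read_mutations(path) -> pd.DataFrame:
    """Read a long-format mutation table: sample_id, gene, status."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for required in ("sample_id", "gene", "status"):
        if required not in cols:
            raise FormatError(f"{path}: missing column {required!r}")
    out = df.rename(columns={cols["sample_id"]: "sample_id",
                             cols["gene"]: "gene",
                             cols["status"]: "status"})
    bad = ~out["status"].isin(MUTATION_STATUSES)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise FormatError(f"{path}, line {row + 2}: unknown mutation status "
                          f"{out['status'].iloc[row]!r}")
    if out.duplicated(["sample_id", "gene"]).any():
        row = int(np.flatnonzero(out.duplicated(['sample_id', 'gene']))[0])
        raise FormatError(f"{path}, line {row + 2}: duplicate (sample, gene) "
                          f"pair")
    return out[["sample_id", "gene", "status"]]


def write_mutations(mutations: pd.DataFrame, path) -> None:
    mutations[["sample_id", "gene", "status"]].to_csv(path, sep="\t",
                                                      index=False)


def read_dependencies(path) -> pd.DataFrame:
    """Read a dependency screen: cell_line, gene, t_statistic, perturbation."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for required in ("cell_line", "gene", "t_statistic", "perturbation"):
        if required not in cols:
            raise FormatError(f"{path}: missing column {required!r}")
    out = df.rename(columns={cols[c]: c for c in
                             ("cell_line", "gene", "t_statistic",
                              "perturbation")})
    try:
        t = out["t_statistic"].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric T-statistic ({exc})") from exc
    if not np.isfinite(t).all():
        row = int(np.flatnonzero(~np.isfinite(t))[0])
        raise FormatError(f"{path}, line {row + 2}: non-finite T-statistic")
    out["t_statistic"] = t
    bad = ~out["perturbation"].isin(PERTURBATIONS)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise FormatError(f"{path}, line {row + 2}: unknown perturbation "
                          f"{out['perturbation'].iloc[row]!r}")
    return out[["cell_line", "gene", "t_statistic", "perturbation"]]


def write_dependencies(dependencies: pd.DataFrame, path) -> None:
    dependencies[["cell_line", "gene", "t_statistic", "perturbation"]].to_csv(
        path, sep="\t", index=False)


def check_sample_overlap(expression: pd.DataFrame,
                         clinical: pd.DataFrame) -> dict:
    """Report (never silently drop) samples missing from either table."""
    expr_ids = set(expression.columns)
    clin_ids = set(clinical["sample_id"])
    return {
        "shared": sorted(expr_ids & clin_ids),
        "clinical_only": sorted(clin_ids - expr_ids),
        "expression_only": sorted(expr_ids - clin_ids),
    }


def log2_transform(expression: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) transform used before z-scoring; rank statistics are
    invariant to it, z-scores are not."""
    return np.log2(expression + 1.0)
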