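"""Readers and writers for the pipeline's plain-text formats.

TSV everywhere; gene sets as GMT; configuration and manifests as YAML. Every
writer's output round-trips through its reader to an equal in-memory value.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ora import ORAResult, SweepResult
from .synthetic import (
    ExpressionPanel,
    GeneCatalog,
    GeneSetCollection,
    QTLRegionSet,
)

_LENGTHS_PREFIX = "# chrom_lengths_cM:"


# -- gene catalog -----------------------------------------------------------


def write_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_LENGTHS_PREFIX + " " + ",".join(
            repr(float(x)) for x in catalog.chrom_lengths_cM) + "\n")
        catalog.table.to_csv(fh, sep="\t", index=False)


def read_catalog(path: str | Path) -> GeneCatalog:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith(_LENGTHS_PREFIX):
            raise ValueError(f"{path}: missing chromosome-length header line")
        lengths = tuple(float(x) for x in first[len(_LENGTHS_PREFIX):].split(","))
        table = pd.read_csv(fh, sep="\t")
    table["is_duplicated"] = table["is_duplicated"].astype(bool)
    return GeneCatalog(table=table, chrom_lengths_cM=lengths)


# -- expression panels ------------------------------------------------------


def write_panel(panel: ExpressionPanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, sep="\t")


def read_panel(path: str | Path) -> ExpressionPanel:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    genotypes, times, reps = [], [], []
    for name in frame.columns:
        geno, t, r = name.split("_")
        genotypes.append(geno)
        times.append(int(t[1:]))
        reps.append(int(r[1:]))
    genos = set(genotypes)
    if len(genos) != 1:
        raise ValueError(f"{path}: mixed genotypes in one panel: {sorted(genos)}")
    return ExpressionPanel(
        genotype=genotypes[0],
        values=frame.to_numpy().T,
        gene_ids=tuple(frame.index),
        time=np.array(times),
        replicate=np.array(reps),
    )


# -- QTL regions and gene lists ---------------------------------------------


def write_qtl_regions(qtl: QTLRegionSet, path: str | Path) -> None:
    qtl.regions.to_csv(path, sep="\t", index=False)


def read_qtl_regions(path: str | Path, catalog: GeneCatalog) -> QTLRegionSet:
    from .synthetic import _genes_in_regions

    regions = pd.read_csv(path, sep="\t")
    regions["chromosome"] = regions["chromosome"].astype(int)
    return QTLRegionSet(regions=regions, test_set=_genes_in_regions(catalog, regions))


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


# -- gene set collections (GMT) ---------------------------------------------

_PLANTED_DESC = "planted_enriched"
_DEFAULT_DESC = "synthetic_pathway"


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(collection.sets):
            desc = _PLANTED_DESC if name == collection.planted_enriched else _DEFAULT_DESC
            members = "\t".join(collection.sets[name])
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, ...]] = {}
    planted = None
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: GMT line with fewer than 3 fields")
        name, desc, members = fields[0], fields[1], fields[2:]
        sets[name] = tuple(members)
        if desc == _PLANTED_DESC:
            planted = name
    return GeneSetCollection(sets=sets, planted_enriched=planted)


# -- sweep tables ------------------------------------------------------------


def write_sweep(sweep: SweepResult, path: str | Path) -> None:
    sweep.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sweep(path: str | Path, a: int, t: int) -> SweepResult:
    frame = pd.read_csv(path, sep="\t", na_values="NA")
    results = []
    for _, row in frame.iterrows():
        results.append(
            ORAResult(
                a=a,
                t=t,
                n=int(row["n_set"]),
                k=int(row["k"]),
                k_expected=float(row["k_expected"]),
                p_value=None if pd.isna(row["p_value"]) else float(row["p_value"]),
                enrichment_fraction=(
                    None if pd.isna(row["enrichment_fraction"])
                    else float(row["enrichment_fraction"])
                ),
            )
        )
    return SweepResult(grid=tuple(int(x) for x in frame["n_top"]), results=tuple(results))


# -- scores / h-tables -------------------------------------------------------


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA")


# -- config and manifest -----------------------------------------------------


def load_config(path: str | Path, required: tuple[str, ...] = ("seed", "outdir")) -> dict:
    with Path(path).open() as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    for key in required:
        if key not in config:
            raise ValueError(f"config missing required key: {key!r}")
    return config


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)
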