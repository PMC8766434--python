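"""Plain-text I/O: expression/annotation TSV and GCT-like catalogs.

Expression TSV: genes as rows, samples as columns, first column the gene id.
Annotation TSV: samples as rows. GCT-like catalog: a ``#1.2`` header line, a
dimension line, then id/description columns followed by one column per
perturbagen; perturbagen type and declared target ride in two leading
metadata rows.
"""

from __future__ import annotations

import pandas as pd

from .containers import ExpressionCompendium, PerturbationCatalog


def write_expression_tsv(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="sample_id")


def read_annotation_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_compendium(compendium: ExpressionCompendium, expr_path, ann_path) -> None:
    write_expression_tsv(compendium.values, expr_path)
    write_annotation_tsv(compendium.annotation, ann_path)


def read_compendium(expr_path, ann_path) -> ExpressionCompendium:
    return ExpressionCompendium(
        read_expression_tsv(expr_path), read_annotation_tsv(ann_path)
    )


def write_catalog_gct(catalog: PerturbationCatalog, path) -> None:
    sig = catalog.signatures
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{sig.shape[0]}\t{sig.shape[1]}\n")
        cols = "\t".join(sig.columns)
        fh.write(f"id\tdescription\t{cols}\n")
        fh.write("type\tna\t" + "\t".join(catalog.meta.loc[c, 'type'] for c in sig.columns) + "\n")
        fh.write("target\tna\t" + "\t".join(str(catalog.meta.loc[c, 'target']) for c in sig.columns) + "\n")
        for gene, row in sig.iterrows():
            fh.write(f"{gene}\t{gene}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_catalog_gct(path) -> PerturbationCatalog:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#1.2"):
            raise ValueError("not a GCT-like file (missing #1.2 header)")
        fh.readline()  # dimensions
        names = fh.readline().rstrip("\n").split("\t")[2:]
        types = fh.readline().rstrip("\n").split("\t")[2:]
        targets = fh.readline().rstrip("\n").split("\t")[2:]
        body = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    sig = body.iloc[:, 1:]
    sig.columns = names
    sig.index.name = "gene_id"
    meta = pd.DataFrame(
        {"type": types, "target": ["" if t == "nan" else t for t in targets]},
        index=pd.Index(names, name="perturbagen"),
    )
    return PerturbationCatalog(sig.astype(float), meta)
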