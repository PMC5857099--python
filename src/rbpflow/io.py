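"""Readers and writers for the plain-text interchange formats.

Matrices travel as TSV with genes/transcripts in rows and a header of sample
ids; group labels as two-column TSV; gene lists as one id per line; peaks as
BED6; gene models as GTF restricted to gene/exon/CDS features; configs as
YAML.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .targets import GeneModel, Peak

logger = logging.getLogger(__name__)


def read_matrix(path) -> pd.DataFrame:
    """Genes x samples TSV with the gene id in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
    logger.info("wrote matrix %s (%d x %d)", path, *df.shape)


def read_groups(path) -> pd.Series:
    """Two-column TSV: sample id, group label."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_groups(groups: pd.Series, path) -> None:
    groups.rename("group").to_csv(path, sep="\t", index_label="sample")
    logger.info("wrote groups %s", path)


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
    logger.info("wrote gene list %s", path)


def write_bed6(peaks: Iterable[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\t0\t+\n")
    logger.info("wrote BED %s", path)


def write_gtf(models: Iterable[GeneModel], path) -> None:
    """GTF (1-based closed) with gene, exon, and CDS features only."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.transcript_id}"; transcript_id "{m.transcript_id}";'
            rows = [("gene", m.start, m.end)]
            rows += [("exon", s, e) for s, e in m.exons]
            rows.append(("CDS", m.cds[0], m.cds[1]))
            for feature, start, end in rows:
                fh.write(
                    f"{m.chrom}\trbpflow\t{feature}\t{start + 1}\t{end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
    logger.info("wrote GTF %s", path)


def write_config(config: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
    logger.info("wrote config %s", path)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
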