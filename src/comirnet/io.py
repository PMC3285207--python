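"""Readers and writers for every on-disk format the pipeline touches.

All formats are plain text: expression TSV (first column = feature ID,
header row = sample IDs), probe-map TSV, FASTA, GMT gene sets, simple
key/value annotation TSVs, and JSON for ground truth and manifests.
Floats are written with a fixed format so reruns are byte-identical.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ExpressionMatrix
from .orthology import OrthologyMap

FLOAT_FORMAT = "%.10g"


# -- expression -------------------------------------------------------------

def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    df = m.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_expression_tsv(path, species: str = "", dataset_id: str = "") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, species=species, dataset_id=dataset_id or Path(path).stem)


# -- probe map --------------------------------------------------------------

def write_probe_map_tsv(probe_map: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("probe\tmirnas\n")
        for probe in probe_map:
            fh.write(f"{probe}\t{','.join(probe_map[probe])}\n")


def read_probe_map_tsv(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        targets = [] if pd.isna(row.mirnas) else str(row.mirnas).split(",")
        out[str(row.probe)] = [t for t in targets if t]
    return out


# -- FASTA ------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- GMT --------------------------------------------------------------------

def write_gmt(gene_sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name in gene_sets:
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\tsynthetic\t{genes}\n")


def read_gmt(path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(parts[2:])
    return out


# -- annotation tables ------------------------------------------------------

def write_locations_tsv(locations: Mapping[str, tuple[str, int, int, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tchrom\tstart\tend\tstrand\n")
        for mir in locations:
            chrom, start, end, strand = locations[mir]
            fh.write(f"{mir}\t{chrom}\t{start}\t{end}\t{strand}\n")


def read_locations_tsv(path) -> dict[str, tuple[str, int, int, str]]:
    df = pd.read_csv(path, sep="\t", dtype={"mirna": str, "chrom": str, "strand": str})
    return {
        str(r.mirna): (str(r.chrom), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples(index=False)
    }


def write_mapping_tsv(mapping: Mapping[str, str], path, key: str, value: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{key}\t{value}\n")
        for k in mapping:
            fh.write(f"{k}\t{mapping[k]}\n")


def read_mapping_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    return {str(r[0]): str(r[1]) for r in df.itertuples(index=False)}


def write_pairs_tsv(pairs: Iterable[tuple[str, str]], path, cols: tuple[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write(f"{cols[0]}\t{cols[1]}\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_pairs_tsv(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [(str(r[0]), str(r[1])) for r in df.itertuples(index=False)]


def write_disease_tsv(disease: Mapping[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tdisease\n")
        for mir in sorted(disease):
            for d in sorted(disease[mir]):
                fh.write(f"{mir}\t{d}\n")


def read_disease_tsv(path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for mir, d in read_pairs_tsv(path):
        out.setdefault(mir, set()).add(d)
    return out


def write_fc_tables_tsv(fc: Mapping[str, Mapping[str, Mapping[str, float]]], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tcell_line\tgene\tfold_change\n")
        for mir in sorted(fc):
            for cell in sorted(fc[mir]):
                for gene in sorted(fc[mir][cell]):
                    fh.write(f"{mir}\t{cell}\t{gene}\t{fc[mir][cell][gene]:.6g}\n")


def read_fc_tables_tsv(path) -> dict[str, dict[str, dict[str, float]]]:
    df = pd.read_csv(path, sep="\t", dtype={"mirna": str, "cell_line": str, "gene": str})
    out: dict[str, dict[str, dict[str, float]]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.mirna, {}).setdefault(r.cell_line, {})[r.gene] = float(r.fold_change)
    return out


def write_target_scores_tsv(scores: Mapping[str, Mapping[str, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tgene\tcontext_score\n")
        for mir in sorted(scores):
            for gene in sorted(scores[mir]):
                fh.write(f"{mir}\t{gene}\t{scores[mir][gene]:.6g}\n")


def read_target_scores_tsv(path) -> dict[str, dict[str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"mirna": str, "gene": str})
    out: dict[str, dict[str, float]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.mirna, {})[r.gene] = float(r.context_score)
    return out


# -- orthology --------------------------------------------------------------

def write_orthology_tsv(omap: OrthologyMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("species1\tspecies2\tscore\tseed\tusable\n")
        for pair in omap.pairs:
            score, seed = omap.provenance.get(pair, (float("nan"), ""))
            usable = omap.usable.get(pair, True)
            fh.write(f"{pair[0]}\t{pair[1]}\t{score:.6g}\t{seed}\t{int(usable)}\n")


def read_orthology_tsv(path) -> OrthologyMap:
    df = pd.read_csv(path, sep="\t", dtype={"species1": str, "species2": str, "seed": str})
    pairs = []
    provenance = {}
    usable = {}
    for r in df.itertuples(index=False):
        pair = (str(r.species1), str(r.species2))
        pairs.append(pair)
        provenance[pair] = (float(r.score), "" if pd.isna(r.seed) else str(r.seed))
        usable[pair] = bool(int(r.usable))
    return OrthologyMap(pairs=pairs, provenance=provenance, usable=usable)


def write_precursor_mature_tsv(mapping: Mapping[str, list], path) -> None:
    with open(path, "w") as fh:
        fh.write("precursor\tmature\tarm\n")
        for prec in mapping:
            for mature, arm in mapping[prec]:
                fh.write(f"{prec}\t{mature}\t{arm or ''}\n")


def read_precursor_mature_tsv(path) -> dict[str, list[tuple[str, str | None]]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[tuple[str, str | None]]] = {}
    for r in df.itertuples(index=False):
        arm = None if pd.isna(r.arm) else str(r.arm)
        out.setdefault(str(r.precursor), []).append((str(r.mature), arm))
    return out


# -- JSON -------------------------------------------------------------------

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)!r}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
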