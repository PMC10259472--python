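"""Readers and writers for the pipeline's file formats.

Hit tables are BLAST 12-column tabular dialects with extra columns
(subject length, taxonomy); genome annotations are GFF3; depth tracks are
BED-like windows; trees are newick via dendropy; scaffolds are FASTA via
Biopython. BLAST's 1-based inclusive coordinates are converted to
0-based half-open intervals here, at the boundary, and nowhere else.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .confidence import DepthTrack
from .detection import CandidateLocus, TaxHitSummary, ViralHit

VIRAL_HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "slen", "sspecies", "sfamily", "sstructure",
]

TE_HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

NR_HIT_COLUMNS = ["qseqid", "sseqid", "bitscore", "superkingdom", "order", "species"]


def _to_half_open(start_1based: int, end_1based: int) -> tuple[int, int]:
    lo, hi = sorted((int(start_1based), int(end_1based)))
    return lo - 1, hi


def read_viral_hits(path: str | os.PathLike) -> list[ViralHit]:
    """Read the viral hit table (BLAST tabular + slen/taxonomy columns).

    Malformed rows are skipped with a warning column in the log rather
    than aborting the run.
    """
    df = pd.read_csv(path, sep="\t", names=VIRAL_HIT_COLUMNS, comment="#")
    hits = []
    for row in df.itertuples(index=False):
        start, end = _to_half_open(row.qstart, row.qend)
        coverage = 100.0 * row.length / row.slen if row.slen > 0 else 0.0
        hits.append(
            ViralHit(
                scaffold_id=str(row.qseqid),
                start=start,
                end=end,
                viral_protein_id=str(row.sseqid),
                viral_species=str(row.sspecies),
                viral_family=str(row.sfamily),
                genomic_structure=str(row.sstructure),
                e_value=float(row.evalue),
                bit_score=float(row.bitscore),
                pct_identity=float(row.pident),
                pct_viral_protein_coverage=min(100.0, coverage),
            )
        )
    return hits


def write_viral_hits(hits: Sequence[ViralHit], path: str | os.PathLike) -> None:
    rows = []
    for h in hits:
        # subject length 10000 keeps the written coverage faithful to 0.01%
        aln_len = int(round(h.pct_viral_protein_coverage / 100.0 * 10_000))
        rows.append(
            {
                "qseqid": h.scaffold_id,
                "sseqid": h.viral_protein_id,
                "pident": h.pct_identity,
                "length": aln_len,
                "mismatch": 0,
                "gapopen": 0,
                "qstart": h.start + 1,
                "qend": h.end,
                "sstart": 1,
                "send": aln_len,
                "evalue": h.e_value,
                "bitscore": h.bit_score,
                "slen": 10_000,
                "sspecies": h.viral_species,
                "sfamily": h.viral_family,
                "sstructure": h.genomic_structure,
            }
        )
    pd.DataFrame(rows, columns=VIRAL_HIT_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_te_hits(path: str | os.PathLike) -> pd.DataFrame:
    """TE protein hits; 'length' is the aligned query length in amino
    acids, qstart/qend are scaffold coordinates (converted to 0-based
    half-open columns 'start'/'end')."""
    df = pd.read_csv(path, sep="\t", names=TE_HIT_COLUMNS, comment="#")
    lo = df[["qstart", "qend"]].min(axis=1) - 1
    hi = df[["qstart", "qend"]].max(axis=1)
    df["start"], df["end"] = lo, hi
    return df


def write_te_hits(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[TE_HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_nr_hits(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=NR_HIT_COLUMNS, comment="#")


def write_nr_hits(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[NR_HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def summarize_nr_hits(
    nr: pd.DataFrame, min_viral_bits: float = 50.0
) -> dict[str, TaxHitSummary]:
    """Aggregate raw generalist hits into per-scaffold taxonomic summaries.

    Hymenoptera hits are excluded here so that shared endogenizations
    present in database wasps never count against a locus.
    """
    out: dict[str, TaxHitSummary] = {}
    for scaffold, grp in nr.groupby("qseqid"):
        sk = grp["superkingdom"].str.lower()
        hymenoptera = grp["order"].str.lower() == "hymenoptera"
        euk = ((sk == "eukaryota") & ~hymenoptera).sum()
        prok = sk.isin(["bacteria", "archaea", "prokaryota"]).sum()
        viral = grp[(sk == "viruses") & (grp["bitscore"] >= min_viral_bits)]
        out[str(scaffold)] = TaxHitSummary(
            n_euk_non_hym_hits=int(euk),
            n_prok_hits=int(prok),
            n_distinct_viral_species_bits50=int(viral["species"].nunique()),
        )
    return out


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

def write_gff3(records: Sequence[dict], path: str | os.PathLike) -> None:
    """Write gene features. Each record: scaffold, start, end (0-based
    half-open), feature type, and an attribute dict (taxonomy, busco, ID)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = ";".join(f"{k}={v}" for k, v in r.get("attributes", {}).items())
            fh.write(
                "\t".join(
                    [
                        r["scaffold"],
                        "endovir_sim",
                        r.get("type", "gene"),
                        str(r["start"] + 1),
                        str(r["end"]),
                        ".",
                        r.get("strand", "+"),
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | os.PathLike) -> pd.DataFrame:
    """Read GFF3 into a frame with 0-based half-open start/end and parsed
    'taxonomy' and 'busco' attribute columns."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=[
            "scaffold", "source", "type", "start1", "end", "score",
            "strand", "phase", "attributes",
        ],
        dtype={"scaffold": str},
    )
    df["start"] = df["start1"] - 1
    def attr(s: str, key: str) -> str:
        for part in str(s).split(";"):
            if part.startswith(key + "="):
                return part.split("=", 1)[1]
        return ""
    df["taxonomy"] = df["attributes"].map(lambda s: attr(s, "taxonomy"))
    df["busco"] = df["attributes"].map(lambda s: attr(s, "busco") == "true")
    return df


# ---------------------------------------------------------------------------
# depth tracks (BED-like windows)
# ---------------------------------------------------------------------------

def write_depth_bed(tracks: Sequence[DepthTrack], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for tr in tracks:
            for s, e, d in zip(tr.starts, tr.ends, tr.depths):
                fh.write(f"{tr.scaffold_id}\t{int(s)}\t{int(e)}\t{d:.4f}\n")


def read_depth_bed(path: str | os.PathLike) -> dict[str, DepthTrack]:
    df = pd.read_csv(
        path, sep="\t", names=["scaffold", "start", "end", "depth"], dtype={"scaffold": str}
    )
    out = {}
    for scaffold, grp in df.groupby("scaffold", sort=False):
        grp = grp.sort_values("start")
        out[str(scaffold)] = DepthTrack(
            scaffold_id=str(scaffold),
            starts=grp["start"].to_numpy(),
            ends=grp["end"].to_numpy(),
            depths=grp["depth"].to_numpy(dtype=float),
        )
    return out


# ---------------------------------------------------------------------------
# FASTA / trees / simple tables
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
        str(path),
        "fasta",
    )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_tree(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_lifestyles(path: str | os.PathLike) -> pd.DataFrame:
    """Species-lifestyle table: species, lifestyle, optional eusocial
    column splitting free-living species, optional host family and
    source columns."""
    return pd.read_csv(path, sep="\t")


def write_loci(loci: Sequence[CandidateLocus], path: str | os.PathLike) -> None:
    """Candidate loci as TSV with assigned family/structure (BED-style
    coordinates)."""
    rows = [
        {
            "scaffold": lc.scaffold_id,
            "start": lc.start,
            "end": lc.end,
            "n_hits": len(lc.hits),
            "best_protein": lc.best_hit.viral_protein_id,
            "best_evalue": lc.best_hit.e_value,
            "family": lc.assigned_family,
            "structure": lc.assigned_structure,
        }
        for lc in loci
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
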