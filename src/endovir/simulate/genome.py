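"""Synthetic genome bundles: scaffolds with planted EVEs, depth tracks,
annotations and hit tables, plus the truth table that downstream modules
are scored against.

The bundle emulates the statistical structure the detection and scoring
stages assume: host scaffolds at a common sequencing depth carrying BUSCO
genes, insect genes and TE protein hits; viral-contaminant scaffolds at a
divergent depth with neither genes nor TEs; planted EVE insertions whose
homology-hit parameters straddle the filtering thresholds (every planted
EVE keeps at least one passing hit); and decoy loci — host genes with
spurious viral similarity and a eukaryote-heavy generalist-hit profile —
that the taxonomic screen must remove.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .. import io as evio
from ..confidence import DepthTrack
from ..detection import ViralHit
from .config import GenomeSpec, DepthModel, PlantedEve, SimulationConfig

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass
class GenomeBundle:
    scaffolds: dict[str, str]
    depth_tracks: dict[str, DepthTrack]
    genes: list[dict]
    te_hits: pd.DataFrame
    viral_hits: list[ViralHit]
    nr_hits: pd.DataFrame
    truth: pd.DataFrame
    species: str = "sp001"
    busco_scaffolds: list[str] = field(default_factory=list)

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        evio.write_fasta(self.scaffolds, os.path.join(outdir, "scaffolds.fasta"))
        evio.write_depth_bed(
            list(self.depth_tracks.values()), os.path.join(outdir, "depth.bed")
        )
        evio.write_gff3(self.genes, os.path.join(outdir, "genes.gff3"))
        evio.write_te_hits(self.te_hits, os.path.join(outdir, "te_hits.tsv"))
        evio.write_viral_hits(self.viral_hits, os.path.join(outdir, "viral_hits.tsv"))
        evio.write_nr_hits(self.nr_hits, os.path.join(outdir, "nr_hits.tsv"))
        self.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)


_FAMILY_CATALOGUE = [
    ("Nudiviridae", "dsDNA"),
    ("LbFV-like", "dsDNA"),
    ("Baculoviridae", "dsDNA"),
    ("Poxviridae", "dsDNA"),
    ("Iridoviridae", "dsDNA"),
    ("AmFV-like", "dsDNA"),
    ("Parvoviridae", "ssDNA"),
    ("Circoviridae", "ssDNA"),
    ("Bidnaviridae", "ssDNA"),
    ("Reoviridae", "dsRNA"),
    ("Partitiviridae", "dsRNA"),
    ("Birnaviridae", "dsRNA"),
    ("Rhabdoviridae", "ssRNA(-)"),
    ("Orthomyxoviridae", "ssRNA(-)"),
    ("Phenuiviridae", "ssRNA(-)"),
    ("Iflaviridae", "ssRNA(+)"),
    ("Dicistroviridae", "ssRNA(+)"),
    ("Flaviviridae", "ssRNA(+)"),
]


def load_bundle(indir: str | os.PathLike, species: str = "sp001") -> GenomeBundle:
    """Load a bundle previously written with :meth:`GenomeBundle.write`.

    Works equally on real data laid out in the same formats (FASTA +
    depth BED + GFF3 + hit tables); the truth table is optional.
    """
    indir = str(indir)
    scaffolds = evio.read_fasta(os.path.join(indir, "scaffolds.fasta"))
    tracks = evio.read_depth_bed(os.path.join(indir, "depth.bed"))
    gff = evio.read_gff3(os.path.join(indir, "genes.gff3"))
    genes = [
        {
            "scaffold": row.scaffold,
            "start": int(row.start),
            "end": int(row.end),
            "type": row.type,
            "attributes": {
                "taxonomy": row.taxonomy,
                "busco": "true" if row.busco else "false",
            },
        }
        for row in gff.itertuples(index=False)
    ]
    truth_path = os.path.join(indir, "truth.tsv")
    truth = (
        pd.read_csv(truth_path, sep="\t")
        if os.path.exists(truth_path)
        else pd.DataFrame(columns=["scaffold", "start", "end", "expected_class"])
    )
    busco = sorted(gff.loc[gff["busco"], "scaffold"].unique())
    return GenomeBundle(
        scaffolds=scaffolds,
        depth_tracks=tracks,
        genes=genes,
        te_hits=evio.read_te_hits(os.path.join(indir, "te_hits.tsv")),
        viral_hits=evio.read_viral_hits(os.path.join(indir, "viral_hits.tsv")),
        nr_hits=evio.read_nr_hits(os.path.join(indir, "nr_hits.tsv")),
        truth=truth,
        species=species,
        busco_scaffolds=busco,
    )


def default_planted_eves(
    spec: GenomeSpec, n_eves: int = 20, seed: int = 0
) -> list[PlantedEve]:
    """A default planting layout grouping EVEs into events.

    The layout is constructed to agree with the within-species
    aggregation rules, so the truth table is the exact target partition:
    every event receives a distinct viral family, and no two events of
    the same genomic structure share a scaffold. Events alternate between
    a two-EVE single-scaffold pattern, a singleton, and a two-scaffold
    pattern held together by the shared family.
    """
    rng = np.random.default_rng(seed)
    host = [f"scaf{i + 1:03d}" for i in range(spec.n_host_scaffolds)]
    candidates = host[spec.n_busco_scaffolds :] or host
    scaffold_structures: dict[str, set[str]] = {s: set() for s in candidates}
    used_intervals: dict[str, list[tuple[int, int]]] = {s: [] for s in candidates}
    planted: list[PlantedEve] = []
    event_no = 0

    def pick_scaffold(struct: str) -> str:
        fresh = [s for s in candidates if not scaffold_structures[s]]
        if fresh:
            return fresh[int(rng.integers(len(fresh)))]
        compatible = [s for s in candidates if struct not in scaffold_structures[s]]
        if not compatible:
            raise ValueError(
                "not enough scaffolds to plant events without violating the "
                "same-scaffold/same-structure aggregation rule"
            )
        return compatible[int(rng.integers(len(compatible)))]

    def place(scaffold: str) -> tuple[int, int]:
        for _ in range(200):
            length = int(rng.integers(600, 1500))
            start = int(rng.integers(2000, spec.scaffold_length - 2000 - length))
            if all(
                not (start < e and s < start + length)
                for s, e in used_intervals[scaffold]
            ):
                used_intervals[scaffold].append((start, start + length))
                return start, start + length
        raise ValueError(f"could not place a non-overlapping EVE on {scaffold}")

    while len(planted) < n_eves:
        if event_no >= len(_FAMILY_CATALOGUE):
            raise ValueError(
                f"default layout supports at most {len(_FAMILY_CATALOGUE)} events"
            )
        fam, struct = _FAMILY_CATALOGUE[event_no]
        event_no += 1
        event_id = f"event{event_no:02d}"
        kind = event_no % 3  # 0: pair on one scaffold, 1: singleton, 2: two scaffolds
        n_in_event = min(2 if kind != 1 else 1, n_eves - len(planted))
        scaffold = pick_scaffold(struct)
        scaffold_structures[scaffold].add(struct)
        for j in range(n_in_event):
            if kind == 2 and j == 1:
                scaffold_j = pick_scaffold(struct)
                scaffold_structures[scaffold_j].add(struct)
            else:
                scaffold_j = scaffold
            start, end = place(scaffold_j)
            planted.append(
                PlantedEve(
                    scaffold=scaffold_j,
                    start=start,
                    end=end,
                    family=fam,
                    structure=struct,
                    event_id=event_id,
                    domesticated=bool(rng.uniform() < 0.3),
                )
            )
    return planted


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(4, size=length)]


def simulate_genome_bundle(config: SimulationConfig) -> GenomeBundle:
    """Generate every per-genome input file the pipeline consumes."""
    config.validate()
    spec: GenomeSpec = config.genome_spec
    depth: DepthModel = config.depth_model
    rng = np.random.default_rng(config.seed)

    host_ids = [f"scaf{i + 1:03d}" for i in range(spec.n_host_scaffolds)]
    cont_ids = [f"contam{i + 1:03d}" for i in range(spec.n_contaminant_scaffolds)]
    busco_ids = host_ids[: spec.n_busco_scaffolds]

    planted = spec.planted_eves or default_planted_eves(
        spec, n_eves=spec.n_planted_eves, seed=int(rng.integers(2**31 - 1))
    )
    for p in planted:
        if p.scaffold not in host_ids:
            raise ValueError(f"planted EVE on unknown scaffold {p.scaffold}")
        if not (0 <= p.start < p.end <= spec.scaffold_length):
            raise ValueError(
                f"planted EVE [{p.start}, {p.end}) outside scaffold bounds"
            )
    by_scaffold: dict[str, list[PlantedEve]] = {}
    for p in planted:
        for q in by_scaffold.get(p.scaffold, []):
            if p.start < q.end and q.start < p.end:
                raise ValueError(
                    f"overlapping planted EVEs on {p.scaffold}: "
                    f"[{p.start},{p.end}) vs [{q.start},{q.end})"
                )
        by_scaffold.setdefault(p.scaffold, []).append(p)

    # --- sequences, with a shared repeat library driving synteny noise ----
    repeats = [_random_sequence(rng, 500) for _ in range(3)]
    scaffolds: dict[str, str] = {}
    for sid in host_ids:
        length = spec.busco_scaffold_length if sid in busco_ids else spec.scaffold_length
        arr = _random_sequence(rng, length)
        n_rep = int(spec.repeat_density * length / 500)
        for _ in range(n_rep):
            rep = repeats[rng.integers(len(repeats))]
            pos = int(rng.integers(0, length - 500))
            arr[pos : pos + 500] = rep
        scaffolds[sid] = "".join(arr)
    for sid in cont_ids:
        scaffolds[sid] = "".join(_random_sequence(rng, spec.contaminant_length))

    # --- depth tracks ----------------------------------------------------
    tracks: dict[str, DepthTrack] = {}
    for sid, seq in scaffolds.items():
        mean = depth.contaminant_depth if sid in cont_ids else depth.host_mean_depth
        starts = np.arange(0, len(seq), depth.window)
        ends = np.minimum(starts + depth.window, len(seq))
        vals = np.maximum(rng.normal(mean, depth.noise_sd, size=len(starts)), 0.1)
        tracks[sid] = DepthTrack(sid, starts, ends, vals)

    # --- genes (GFF3) and TE hits ----------------------------------------
    genes: list[dict] = []
    te_rows: list[dict] = []
    gene_no = 0
    for sid in host_ids:
        n_genes = max(1, int(rng.poisson(spec.genes_per_scaffold)))
        for _ in range(n_genes):
            gene_no += 1
            gstart = int(rng.integers(0, spec.scaffold_length - 1500))
            taxonomy = "Insecta" if rng.uniform() < 0.9 else "Bacteria"
            genes.append(
                {
                    "scaffold": sid,
                    "start": gstart,
                    "end": gstart + 1200,
                    "type": "gene",
                    "attributes": {
                        "ID": f"gene{gene_no:04d}",
                        "taxonomy": taxonomy,
                        "busco": "false",
                    },
                }
            )
        if sid in busco_ids:
            for _ in range(3):
                gene_no += 1
                gstart = int(rng.integers(0, spec.scaffold_length - 1500))
                genes.append(
                    {
                        "scaffold": sid,
                        "start": gstart,
                        "end": gstart + 1200,
                        "type": "gene",
                        "attributes": {
                            "ID": f"gene{gene_no:04d}",
                            "taxonomy": "Insecta",
                            "busco": "true",
                        },
                    }
                )
        n_te = int(rng.poisson(spec.tes_per_scaffold))
        for t in range(n_te):
            tstart = int(rng.integers(0, spec.scaffold_length - 600))
            qualifying = rng.uniform() < 0.8
            te_rows.append(
                {
                    "qseqid": sid,
                    "sseqid": f"TEprot_{rng.integers(1, 50):03d}#Gypsy/LTR",
                    "pident": float(rng.uniform(30, 80)),
                    "length": int(rng.integers(120, 300)) if qualifying else 80,
                    "mismatch": 0,
                    "gapopen": 0,
                    "qstart": tstart + 1,
                    "qend": tstart + 500,
                    "sstart": 1,
                    "send": 160,
                    "evalue": 1e-20 if qualifying else 1e-6,
                    "bitscore": 120.0,
                }
            )

    # --- viral hits -------------------------------------------------------
    viral_hits: list[ViralHit] = []
    nr_rows: list[dict] = []
    truth_rows: list[dict] = []

    def nr_background(sid: str, n_euk: int, n_prok: int, n_viral: int, n_hym: int = 0):
        for v in range(n_viral):
            nr_rows.append(
                {
                    "qseqid": sid,
                    "sseqid": f"nr_vir_{sid}_{v}",
                    "bitscore": float(rng.uniform(60, 200)),
                    "superkingdom": "Viruses",
                    "order": "na",
                    "species": f"virus_sp_{sid}_{v}",
                }
            )
        for e in range(n_euk):
            nr_rows.append(
                {
                    "qseqid": sid,
                    "sseqid": f"nr_euk_{sid}_{e}",
                    "bitscore": float(rng.uniform(50, 150)),
                    "superkingdom": "Eukaryota",
                    "order": "Diptera",
                    "species": f"euk_sp_{e}",
                }
            )
        for b in range(n_prok):
            nr_rows.append(
                {
                    "qseqid": sid,
                    "sseqid": f"nr_prok_{sid}_{b}",
                    "bitscore": float(rng.uniform(50, 150)),
                    "superkingdom": "Bacteria",
                    "order": "na",
                    "species": f"bact_sp_{b}",
                }
            )
        for hym in range(n_hym):
            nr_rows.append(
                {
                    "qseqid": sid,
                    "sseqid": f"nr_hym_{sid}_{hym}",
                    "bitscore": float(rng.uniform(50, 150)),
                    "superkingdom": "Eukaryota",
                    "order": "Hymenoptera",
                    "species": f"wasp_sp_{hym}",
                }
            )

    def add_hit(sid, start, end, fam, struct, passing, protein, species_name):
        if passing:
            ident = float(rng.uniform(28, 60))
            cov = float(rng.uniform(40, 95))
            e_val = 10.0 ** float(-rng.uniform(8, 60))
            bit = float(rng.uniform(80, 400))
        else:  # straddle one threshold at a time
            which = rng.integers(3)
            ident = float(rng.uniform(10, 19)) if which == 0 else float(rng.uniform(25, 50))
            cov = float(rng.uniform(5, 29)) if which == 1 else float(rng.uniform(35, 90))
            e_val = 10.0 ** float(-rng.uniform(0, 3)) if which == 2 else 1e-10
            bit = float(rng.uniform(30, 60))
        viral_hits.append(
            ViralHit(
                scaffold_id=sid,
                start=start,
                end=end,
                viral_protein_id=protein,
                viral_species=species_name,
                viral_family=fam,
                genomic_structure=struct,
                e_value=e_val,
                bit_score=bit,
                pct_identity=ident,
                pct_viral_protein_coverage=cov,
            )
        )

    for p_no, p in enumerate(planted):
        protein = f"{p.family}_prot{p_no:03d}"
        species_name = f"{p.family}_virus"
        add_hit(p.scaffold, p.start, p.end, p.family, p.structure, True, protein, species_name)
        for extra in range(int(rng.integers(0, 3))):
            lo = int(rng.integers(p.start, max(p.start + 1, p.end - 100)))
            hi = min(p.end, lo + int(rng.integers(100, 800)))
            if hi <= lo:
                continue
            add_hit(
                p.scaffold, lo, hi, p.family, p.structure,
                bool(rng.uniform() < 0.5),
                f"{protein}_alt{extra}", species_name,
            )
        truth_rows.append(
            {
                "scaffold": p.scaffold,
                "start": p.start,
                "end": p.end,
                "family": p.family,
                "structure": p.structure,
                "event_id": p.event_id,
                "domesticated": p.domesticated,
                "expected_class": "eve",
            }
        )

    for sid in sorted(by_scaffold):
        # one generalist-hit background per EVE-bearing scaffold: a few
        # eukaryotic/prokaryotic matches, plenty of viral species
        nr_background(
            sid,
            n_euk=int(rng.integers(0, 5)),
            n_prok=int(rng.integers(0, 2)),
            n_viral=int(rng.integers(10, 20)),
            n_hym=int(rng.integers(0, 4)),
        )

    # decoys: host genes with spurious viral similarity; the generalist
    # screen sees a eukaryote-dominated profile
    decoy_scaffolds = [s for s in host_ids if s not in by_scaffold][: spec.n_decoy_loci]
    for d, sid in enumerate(decoy_scaffolds):
        start = int(rng.integers(0, spec.scaffold_length - 900))
        add_hit(
            sid, start, start + 800, "Mimiviridae", "dsDNA", True,
            f"decoy_prot{d:02d}", "decoy_virus",
        )
        nr_background(sid, n_euk=int(rng.integers(30, 60)), n_prok=5, n_viral=int(rng.integers(0, 5)))
        truth_rows.append(
            {
                "scaffold": sid,
                "start": start,
                "end": start + 800,
                "family": "Mimiviridae",
                "structure": "dsDNA",
                "event_id": "decoy",
                "domesticated": False,
                "expected_class": "decoy",
            }
        )

    for sid in cont_ids:
        for h in range(4):
            start = int(rng.integers(0, spec.contaminant_length - 1200))
            add_hit(
                sid, start, start + 1000, "LbFV-like", "dsDNA", True,
                f"freeliving_prot_{sid}_{h}", "free_living_virus",
            )
            truth_rows.append(
                {
                    "scaffold": sid,
                    "start": start,
                    "end": start + 1000,
                    "family": "LbFV-like",
                    "structure": "dsDNA",
                    "event_id": "contaminant",
                    "domesticated": False,
                    "expected_class": "contaminant",
                }
            )
        nr_background(sid, n_euk=0, n_prok=0, n_viral=15)

    return GenomeBundle(
        scaffolds=scaffolds,
        depth_tracks=tracks,
        genes=genes,
        te_hits=pd.DataFrame(te_rows, columns=evio.TE_HIT_COLUMNS),
        viral_hits=viral_hits,
        nr_hits=pd.DataFrame(nr_rows, columns=evio.NR_HIT_COLUMNS),
        truth=pd.DataFrame(truth_rows),
        busco_scaffolds=busco_ids,
    )
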