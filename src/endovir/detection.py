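"""Candidate EVE detection from viral homology hits.

Raw hits against a viral protein database are filtered on protein
coverage, identity and E-value, merged into candidate loci wherever they
overlap on the same scaffold, and screened against a generalist (Nr-style)
homology summary to discard eukaryotic/prokaryotic false positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .intervals import overlap_components

logger = logging.getLogger(__name__)

GENOMIC_STRUCTURES = ("dsDNA", "ssDNA", "dsRNA", "ssRNA(+)", "ssRNA(-)", "unknown")

#: thresholds a retained viral hit must satisfy (protein coverage %,
#: identity %, E-value); these are the screen's operating point, optimized
#: upstream against known endogenized controls.
MIN_COVERAGE = 30.0
MIN_IDENTITY = 20.0
MAX_EVALUE = 5e-4


@dataclass(frozen=True)
class ViralHit:
    """One homology hit of a viral protein on a genome scaffold."""

    scaffold_id: str
    start: int  # 0-based
    end: int  # half-open
    viral_protein_id: str
    viral_species: str = "unknown"
    viral_family: str = "unknown"
    genomic_structure: str = "unknown"
    e_value: float = 1.0
    bit_score: float = 0.0
    pct_identity: float = 0.0
    pct_viral_protein_coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"hit interval [{self.start}, {self.end}) is empty")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity outside [0, 100]")
        if not 0.0 <= self.pct_viral_protein_coverage <= 100.0:
            raise ValueError("pct_viral_protein_coverage outside [0, 100]")
        if self.e_value < 0:
            raise ValueError("negative E-value")
        if self.genomic_structure not in GENOMIC_STRUCTURES:
            raise ValueError(f"unknown genomic structure {self.genomic_structure!r}")


@dataclass(frozen=True)
class TaxHitSummary:
    """Per-locus summary of generalist homology hits (Hymenoptera excluded).

    Hymenoptera hits are removed upstream (at the reader) so that a shared
    endogenization present in database Hymenoptera genomes does not count
    against the locus.
    """

    n_euk_non_hym_hits: int = 0
    n_prok_hits: int = 0
    n_distinct_viral_species_bits50: int = 0
    hymenoptera_hits_excluded: bool = True

    def __post_init__(self) -> None:
        if min(self.n_euk_non_hym_hits, self.n_prok_hits, self.n_distinct_viral_species_bits50) < 0:
            raise ValueError("negative hit counts")


@dataclass
class CandidateLocus:
    """A merged candidate EVE locus: the union hull of overlapping hits."""

    scaffold_id: str
    start: int
    end: int
    hits: list[ViralHit] = field(default_factory=list)
    assigned_family: str = "unknown"
    assigned_structure: str = "unknown"

    @property
    def best_hit(self) -> ViralHit:
        """Lowest E-value; ties broken by higher bit score."""
        return min(self.hits, key=lambda h: (h.e_value, -h.bit_score))

    @property
    def locus_id(self) -> str:
        return f"{self.scaffold_id}:{self.start}-{self.end}"


def filter_viral_hits(
    hits: Iterable[ViralHit],
    min_cov: float = MIN_COVERAGE,
    min_id: float = MIN_IDENTITY,
    max_e: float = MAX_EVALUE,
) -> list[ViralHit]:
    """Keep hits with coverage >= min_cov, identity >= min_id, E < max_e.

    Order is preserved. Malformed rows are expected to be rejected at the
    reader; here every input is already a validated :class:`ViralHit`.
    """
    for thr in (min_cov, min_id, max_e):
        if not (thr == thr and abs(thr) != float("inf")):
            raise ValueError("thresholds must be finite")
    return [
        h
        for h in hits
        if h.pct_viral_protein_coverage >= min_cov
        and h.pct_identity >= min_id
        and h.e_value < max_e
    ]


def merge_hits_to_loci(hits: Sequence[ViralHit]) -> list[CandidateLocus]:
    """Merge overlapping hits on the same scaffold into candidate loci.

    The merge is the transitive closure of strict overlap; abutting hits
    stay separate. The result does not depend on input order: loci are
    returned sorted by (scaffold, start), hits within a locus by
    (start, end, protein id).
    """
    by_scaffold: dict[str, list[ViralHit]] = {}
    for h in hits:
        by_scaffold.setdefault(h.scaffold_id, []).append(h)
    loci: list[CandidateLocus] = []
    for scaffold in sorted(by_scaffold):
        shits = sorted(
            by_scaffold[scaffold],
            key=lambda h: (h.start, h.end, h.viral_protein_id, h.e_value),
        )
        for idx_group in overlap_components([(h.start, h.end) for h in shits]):
            members = [shits[i] for i in idx_group]
            loci.append(
                CandidateLocus(
                    scaffold_id=scaffold,
                    start=min(h.start for h in members),
                    end=max(h.end for h in members),
                    hits=members,
                )
            )
    return loci


def taxonomic_filter(
    locus: CandidateLocus,
    tax: TaxHitSummary,
    n_viral_hits: int | None = None,
    max_background: int = 25,
    rescue_min_viral_species: int = 10,
    single_hit_max_background: int = 5,
) -> tuple[bool, str]:
    """Decide whether a candidate locus survives the generalist screen.

    Rules:
    * more than *max_background* combined eukaryotic (non-Hymenoptera) +
      prokaryotic hits drop the locus, unless it also matched at least
      *rescue_min_viral_species* distinct viral species with bit >= 50;
    * a locus supported by a single viral hit is kept only when it has at
      most *single_hit_max_background* eukaryotic/prokaryotic hits.

    Returns ``(keep, reason)``.
    """
    if not tax.hymenoptera_hits_excluded:
        raise ValueError("tax summary must exclude Hymenoptera hits")
    background = tax.n_euk_non_hym_hits + tax.n_prok_hits
    if n_viral_hits is None:
        n_viral_hits = len(locus.hits)
    if n_viral_hits < 1:
        raise ValueError("locus without viral hits")
    if background > max_background and tax.n_distinct_viral_species_bits50 < rescue_min_viral_species:
        return False, (
            f"{background} eukaryotic/prokaryotic hits > {max_background} and only "
            f"{tax.n_distinct_viral_species_bits50} distinct viral species (bits >= 50)"
        )
    if n_viral_hits == 1 and background > single_hit_max_background:
        return False, (
            f"single viral hit with {background} eukaryotic/prokaryotic hits "
            f"> {single_hit_max_background}"
        )
    return True, "kept"


def assign_virus(
    locus: CandidateLocus,
    virus_metadata: Mapping[str, tuple[str, str]] | None = None,
) -> CandidateLocus:
    """Assign a viral family and genomic structure from the closest match.

    *virus_metadata* maps viral protein ids (or species names) to
    ``(family, structure)``; when absent, the best hit's own annotation is
    used. Unknowns propagate — the family is never guessed.
    """
    best = locus.best_hit
    family, structure = best.viral_family, best.genomic_structure
    if virus_metadata is not None:
        meta = virus_metadata.get(best.viral_protein_id) or virus_metadata.get(best.viral_species)
        if meta is not None:
            family, structure = meta
        elif family == "unknown":
            logger.warning(
                "no metadata for best hit %s of locus %s; assigning unknown",
                best.viral_protein_id,
                locus.locus_id,
            )
    locus.assigned_family = family or "unknown"
    locus.assigned_structure = structure or "unknown"
    return locus


def drop_te_captured_glycoproteins(
    loci: Sequence[CandidateLocus],
    te_intervals: Mapping[str, Sequence[tuple[int, int]]],
    te_classes: Mapping[str, Sequence[str]] | None = None,
    glycoprotein_marker: str = "chuvirus_glycoprotein",
) -> list[CandidateLocus]:
    """Remove chuviral glycoprotein loci captured by LTR retrotransposons.

    A locus is dropped when its interval overlaps a TE annotation of
    retrotransposon class and its best viral hit is a chuvirus
    glycoprotein — such loci owe their copy number to transposition, not to
    independent endogenizations.
    """
    kept = []
    for locus in loci:
        ivs = te_intervals.get(locus.scaffold_id, ())
        classes = (te_classes or {}).get(locus.scaffold_id, ["retrotransposon"] * len(ivs))
        overlapping_retro = any(
            s < locus.end and locus.start < e
            for (s, e), cls in zip(ivs, classes)
            if "retro" in cls.lower() or "ltr" in cls.lower() or "gypsy" in cls.lower()
        )
        is_glyco = glycoprotein_marker in locus.best_hit.viral_protein_id.lower()
        if overlapping_retro and is_glyco:
            logger.info("dropping TE-captured glycoprotein locus %s", locus.locus_id)
            continue
        kept.append(locus)
    return kept
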