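"""Simulation configuration: the study conditions the generators emulate.

Defaults are scaled to a Hymenoptera-like comparative study: 124 species
sampled from a clade whose crown age is around 280 My, three lifestyles
(free-living as reference, ecto- and endoparasitoid), per-branch dsDNA
endogenization rates of order 1e-2 per My with an endoparasitoid excess,
host sequencing depth near 33x and viral contaminants near 96x.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

LIFESTYLES = ("free_living", "ectoparasitoid", "endoparasitoid")
LIFESTYLES_EUSOCIAL = ("free_living", "eusocial", "ectoparasitoid", "endoparasitoid")


@dataclass
class TreeModel:
    birth_rate: float = 0.0157  # per My; 124-tip Yule crown age ~ 280 My
    death_rate: float = 0.0

    def validate(self) -> None:
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("birth rate must be positive and death rate non-negative")


@dataclass
class PlantedEve:
    scaffold: str
    start: int
    end: int
    family: str = "Nudiviridae"
    structure: str = "dsDNA"
    event_id: str = "event1"
    domesticated: bool = False


@dataclass
class GenomeSpec:
    n_host_scaffolds: int = 20
    scaffold_length: int = 40_000
    n_busco_scaffolds: int = 5
    # BUSCO scaffolds are the long, well-assembled fraction; keeping them
    # longer than candidate scaffolds gives the depth test a rich null of
    # distinct resampled windows
    busco_scaffold_length: int = 200_000
    genes_per_scaffold: float = 3.0
    tes_per_scaffold: float = 2.0
    n_contaminant_scaffolds: int = 2
    contaminant_length: int = 20_000
    n_decoy_loci: int = 3  # eukaryotic genes with spurious viral similarity
    n_planted_eves: int = 20  # used when no explicit planting table is given
    planted_eves: list[PlantedEve] = field(default_factory=list)
    repeat_density: float = 0.05  # fraction of host sequence in repeat copies


@dataclass
class DepthModel:
    host_mean_depth: float = 33.0
    contaminant_depth: float = 95.6
    noise_sd: float = 3.0
    window: int = 1000


@dataclass
class SimulationConfig:
    seed: int = 0
    n_species: int = 124
    tree_model: TreeModel = field(default_factory=TreeModel)
    lifestyle_states: tuple[str, ...] = LIFESTYLES
    # off-diagonal Mk rates, row-major (6 values for 3 states); of order a
    # few lifestyle transitions across the whole clade, matching the deep
    # conservatism of parasitoid lifestyles
    mk_rates: tuple[float, ...] = (0.001,) * 6
    root_state: str = "free_living"
    # the study design samples species of every lifestyle in substantial
    # numbers (free-living/ecto/endo roughly 63/24/37 of 124); simulated
    # histories are redrawn until each lifestyle reaches this tip share
    min_state_tip_fraction: float = 0.15
    # expected events per My of branch, by lifestyle; scaled so a 124-tip
    # tree accumulates a few hundred events, the order observed across all
    # viral structures in a clade-wide screen
    event_rates: dict = field(
        default_factory=lambda: {
            "free_living": 0.030,
            "ectoparasitoid": 0.030,
            "endoparasitoid": 0.075,
        }
    )
    domestication_probs: dict = field(
        default_factory=lambda: {
            "free_living": 0.10,
            "ectoparasitoid": 0.10,
            "endoparasitoid": 0.30,
        }
    )
    zero_inflation: float = 0.2
    # negative-binomial size: mildly overdispersed, near-Poisson; calibrated
    # to the posterior precision the comparative analysis reports on real
    # data (heavier overdispersion would make synthetic counts far noisier
    # than the data the model family was chosen for)
    dispersion: float = 10.0
    genome_spec: GenomeSpec = field(default_factory=GenomeSpec)
    depth_model: DepthModel = field(default_factory=DepthModel)

    def validate(self) -> None:
        self.tree_model.validate()
        if self.n_species < 3:
            raise ValueError("need at least 3 species")
        if any(r < 0 for r in self.mk_rates):
            raise ValueError("Mk rates must be non-negative")
        k = len(self.lifestyle_states)
        if len(self.mk_rates) != k * (k - 1):
            raise ValueError(f"expected {k * (k - 1)} Mk rates for {k} states")
        if self.root_state not in self.lifestyle_states:
            raise ValueError(f"root state {self.root_state!r} not in state list")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion (negative-binomial size) must be positive")
        if any(r < 0 for r in self.event_rates.values()):
            raise ValueError("event rates must be non-negative")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["tree_model"] = TreeModel(**raw.get("tree_model", {}))
        gs = raw.get("genome_spec", {})
        gs["planted_eves"] = [PlantedEve(**p) for p in gs.get("planted_eves", [])]
        raw["genome_spec"] = GenomeSpec(**gs)
        raw["depth_model"] = DepthModel(**raw.get("depth_model", {}))
        raw["lifestyle_states"] = tuple(raw.get("lifestyle_states", LIFESTYLES))
        raw["mk_rates"] = tuple(raw.get("mk_rates", (0.004,) * 6))
        cfg = cls(**raw)
        cfg.validate()
        return cfg
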