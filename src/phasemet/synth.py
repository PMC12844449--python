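"""Ground-truthed synthetic studies: kinetics + replicate noise + peak lists.

Stands in for the unreleased incubation data: a first-order kinetic
network over planted candidate metabolites is sampled on the 1-24 h
grid with three log-normally perturbed replicates, and matching
MS1/MS2 peak lists are emitted with ppm-scale mass jitter so the
annotation and profiling stages can be tested end to end against a
known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import default_fragments, predict_fragments
from .formula import Composition, IonMode, ion_mz
from .kinetics import KineticNetworkSpec, simulate_kinetics
from .parents import ParentCompound, get_parent
from .rules import RuleSet, default_ruleset

__all__ = [
    "NoiseSpec",
    "SyntheticSpecies",
    "SyntheticStudy",
    "sample_study",
    "default_reference_study",
    "two_family_study",
    "DEFAULT_TIME_GRID",
]

DEFAULT_TIME_GRID = (1.0, 2.0, 4.0, 8.0, 12.0, 24.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate and mass-jitter noise model (log-normal x Gaussian ppm)."""

    sigma: float = 0.2  # log-normal sigma on intensities
    mz_ppm_sigma: float = 1.0  # Gaussian ppm jitter on m/z
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0 or self.mz_ppm_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass(frozen=True)
class SyntheticSpecies:
    """One planted species: identity, applied rules and true sites."""

    id: str
    composition: Composition
    assignment: tuple[tuple[str, str], ...] = ()  # (rule_id, moiety)

    @property
    def mz(self) -> float:
        return ion_mz(self.composition, IonMode.PROTONATED)

    @property
    def applied(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.assignment)


@dataclass
class SyntheticStudy:
    parent: str
    scaffold: str
    network: KineticNetworkSpec
    species: dict[str, SyntheticSpecies]
    times: tuple[float, ...]
    noise: NoiseSpec
    trajectories: pd.DataFrame  # noiseless, species x time
    intensities: pd.DataFrame  # long: metabolite_id, time_h, replicate, intensity
    peaks: pd.DataFrame  # id, mz, intensity
    ms2: pd.DataFrame  # precursor_id, mz, intensity
    metadata: dict = field(default_factory=dict)

    def ground_truth(self) -> dict:
        return {
            "parent": self.parent,
            "scaffold": self.scaffold,
            "seed": self.noise.seed,
            "species": {
                s.id: {
                    "formula": s.composition.format(),
                    "mz": round(s.mz, 6),
                    "assignment": [list(pair) for pair in s.assignment],
                }
                for s in self.species.values()
            },
            "edges": [list(e) for e in self.network.edges],
            "elimination": dict(self.network.elimination),
            "times_h": list(self.times),
            "noise": {
                "sigma": self.noise.sigma,
                "mz_ppm_sigma": self.noise.mz_ppm_sigma,
                "replicates": self.noise.replicates,
            },
        }


def _jitter_mz(rng: np.random.Generator, mz: float, ppm_sigma: float) -> float:
    """Gaussian ppm jitter truncated at 4 sigma (redraw)."""
    if ppm_sigma == 0:
        return mz
    d = rng.normal(0.0, ppm_sigma)
    while abs(d) > 4 * ppm_sigma:
        d = rng.normal(0.0, ppm_sigma)
    return mz * (1.0 + d * 1e-6)


def sample_study(
    network: KineticNetworkSpec,
    species: dict[str, SyntheticSpecies],
    noise: NoiseSpec,
    parent: str | ParentCompound | None = None,
    ruleset: RuleSet | None = None,
    times=DEFAULT_TIME_GRID,
    emit_ms2: bool = True,
) -> SyntheticStudy:
    """Sample one seeded study from a kinetic network.

    Intensities are trajectory values times mean-one log-normal noise
    (``exp(N(-sigma^2/2, sigma))``); m/z values carry truncated Gaussian
    ppm jitter.  Everything is deterministic in ``noise.seed``.
    """
    if isinstance(parent, str):
        parent = get_parent(parent)
    scaffold = parent.scaffold if parent else ""
    rng = np.random.default_rng(noise.seed)
    times = tuple(float(t) for t in times)
    traj = simulate_kinetics(network, np.asarray(times))
    traj_df = pd.DataFrame(traj, index=list(network.species), columns=list(times))

    mu = -0.5 * noise.sigma**2
    rows = []
    for sid in network.species:
        base = traj_df.loc[sid].to_numpy()
        for rep in range(1, noise.replicates + 1):
            factors = (
                np.exp(rng.normal(mu, noise.sigma, size=len(times)))
                if noise.sigma > 0
                else np.ones(len(times))
            )
            for t, v in zip(times, base * factors):
                rows.append((sid, t, rep, v))
    intensities = pd.DataFrame(
        rows, columns=["metabolite_id", "time_h", "replicate", "intensity"]
    )

    peak_rows = []
    ms2_rows = []
    frags = losses = None
    if scaffold and emit_ms2:
        frags, losses = default_fragments(scaffold)
        if ruleset is None:
            ruleset = default_ruleset(scaffold)
    for sid in network.species:
        sp = species[sid]
        peak_rows.append(
            (sid, _jitter_mz(rng, sp.mz, noise.mz_ppm_sigma),
             float(traj_df.loc[sid].max()))
        )
        if frags is not None:
            for _label, mz in predict_fragments(
                sp.composition, sp.assignment, ruleset, frags, losses
            ):
                ms2_rows.append((sid, _jitter_mz(rng, mz, noise.mz_ppm_sigma), 100.0))
    peaks = pd.DataFrame(peak_rows, columns=["id", "mz", "intensity"])
    ms2 = pd.DataFrame(ms2_rows, columns=["precursor_id", "mz", "intensity"])

    return SyntheticStudy(
        parent=parent.id if parent else "",
        scaffold=scaffold,
        network=network,
        species=species,
        times=times,
        noise=noise,
        trajectories=traj_df,
        intensities=intensities,
        peaks=peaks,
        ms2=ms2,
        metadata={"generator": "numpy.default_rng(PCG64)", "seed": noise.seed},
    )


def _species_from_assignment(
    sid: str, parent: ParentCompound, rs: RuleSet,
    assignment: tuple[tuple[str, str], ...],
) -> SyntheticSpecies:
    comp = parent.composition
    for rule_id, _moiety in assignment:
        comp = comp.add(rs.get(rule_id).delta)
    return SyntheticSpecies(id=sid, composition=comp, assignment=assignment)


def default_reference_study(
    parent: str = "5F-ADB-PINACA",
    seed: int = 0,
    noise: NoiseSpec | None = None,
) -> SyntheticStudy:
    """Canonical four-species study with known qualitative classes.

    Parent -> persistent hydrolytic-defluorination sink (dominant
    stable), parent -> transient monohydroxy intermediate (early-peak
    decaying) -> depth-3 product (rising).  Rates are chosen so the
    classes are realized noiselessly on the default time grid.
    """
    p = get_parent(parent)
    rs = default_ruleset(p.scaffold)
    if noise is None:
        noise = NoiseSpec(seed=seed)
    elif noise.seed != seed:
        noise = NoiseSpec(
            sigma=noise.sigma, mz_ppm_sigma=noise.mz_ppm_sigma,
            replicates=noise.replicates, seed=seed,
        )
    species = {
        "P": SyntheticSpecies(id="P", composition=p.composition),
        "M_defluoro": _species_from_assignment(
            "M_defluoro", p, rs, (("defluor_oh", "side_chain"),)
        ),
        "M_oh": _species_from_assignment(
            "M_oh", p, rs, (("hydroxylation", "side_chain"),)
        ),
        "M_deep": _species_from_assignment(
            "M_deep",
            p,
            rs,
            (
                ("amide_hydrolysis", "adb_residue"),
                ("dehydrogenation", "adb_residue"),
                ("hydroxylation", "side_chain"),
            ),
        ),
    }
    network = KineticNetworkSpec(
        species=("P", "M_defluoro", "M_oh", "M_deep"),
        edges=(
            ("P", "M_defluoro", 1.2),
            ("P", "M_oh", 0.3),
            ("M_oh", "M_deep", 0.6),
        ),
        parent="P",
    )
    return sample_study(network, species, noise, parent=p, ruleset=rs)


def two_family_study(
    seed: int = 0,
    sigma: float = 0.2,
    replicates: int = 3,
) -> tuple[pd.DataFrame, dict[str, tuple[str, ...]]]:
    """Two planted kinetic families with low cross-correlation.

    Family "rising": terminal sinks of a slowly decaying parent
    (saturating increase).  Family "transient": intermediates peaking
    mid-window and then eliminated.  Returns the long-format intensity
    table (parent excluded) and the family membership map.
    """
    species = ("P", "A1", "A2", "A3", "B1", "B2", "B3")
    network = KineticNetworkSpec(
        species=species,
        edges=(
            ("P", "A1", 0.04),
            ("P", "A2", 0.05),
            ("P", "A3", 0.06),
            ("P", "B1", 0.02),
            ("P", "B2", 0.02),
            ("P", "B3", 0.01),
        ),
        parent="P",
        elimination={"B1": 0.09, "B2": 0.10, "B3": 0.11},
    )
    dummy = {
        sid: SyntheticSpecies(id=sid, composition=Composition({"C": 1}))
        for sid in species
    }
    noise = NoiseSpec(sigma=sigma, mz_ppm_sigma=0.0, replicates=replicates, seed=seed)
    study = sample_study(network, dummy, noise, parent=None, emit_ms2=False)
    long_df = study.intensities[study.intensities["metabolite_id"] != "P"].reset_index(
        drop=True
    )
    families = {"rising": ("A1", "A2", "A3"), "transient": ("B1", "B2", "B3")}
    return long_df, families
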