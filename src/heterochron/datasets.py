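"""Loaders for the packaged study data (events, species, trees, ages).

The two hypothesis topologies are assembled stand-ins (see
``data/README.md``): they encode the molecular (gekkotans-first,
Toxicofera) and morphological (Iguania--Scleroglossa) backbone
hypotheses over the 29 sampled species, not any single published tree.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .chronos import CalibrationTable, read_calibration_table
from .seqdata import Event, Phylogeny
from .synthgen import SimConfig

__all__ = [
    "load_events",
    "load_species",
    "load_hypothesis",
    "load_calibrations",
    "study_sim_config",
    "OUTGROUP",
    "LIMB_EVENTS",
]

OUTGROUP = "Sphenodon_punctatus"
#: limb ridge, limb AER, three-segmented limb, digits differentiated
LIMB_EVENTS = [9, 12, 14, 18]


def _path(name: str):
    return resources.files("heterochron.data").joinpath(name)


def load_events() -> list[Event]:
    df = pd.read_csv(_path("events.tsv"), sep="\t")
    return [Event(int(r["index"]), str(r["label"])) for _, r in df.iterrows()]


def load_species() -> pd.DataFrame:
    return pd.read_csv(_path("species.tsv"), sep="\t")


def load_hypothesis(which: str) -> Phylogeny:
    name = {
        "molecular": "hypothesis_molecular_assembled.nwk",
        "morphological": "hypothesis_morphological_assembled.nwk",
    }.get(which)
    if name is None:
        raise ValueError("which must be 'molecular' or 'morphological'")
    return Phylogeny.from_newick(_path(name).read_text(), outgroup=OUTGROUP)


def load_calibrations() -> CalibrationTable:
    return read_calibration_table(_path("calibrations.csv"))


def study_sim_config(seed: int = 0, tree: Phylogeny | None = None) -> SimConfig:
    """Default synthetic study conditions: 29 species x 20 events on the
    molecular hypothesis, with ties, missing data and limbless snakes.

    Rates reflect what real organogenesis tables look like: frequent
    simultaneity (tie rate 0.15), patchy observation (10% unknown), and a
    sequence-change intensity of 0.5 adjacent transpositions per unit
    branch length.
    """
    if tree is None:
        tree = load_hypothesis("molecular")
    sp = load_species()
    snakes = list(sp.loc[sp["limbless"] == 1, "species"])
    return SimConfig(
        tree=tree,
        n_events=20,
        swap_rate=0.5,
        tie_rate=0.15,
        missing_rate=0.10,
        limbless_tips=snakes,
        limb_events=list(LIMB_EVENTS),
        seed=seed,
    )
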