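"""Trait schemes and per-species categorical trait tables.

A :class:`TraitScheme` declares the categorical traits scored for every
species (for marine molluscs typically body size, life habit, locomotion,
environment and diet) together with the ordered list of states each trait
can take.  A :class:`SpeciesTraitTable` stores, for ``S`` species, the state
index of each trait, and is the common input of the functional-diversity
metrics and the trait-dependent extinction model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Trait", "TraitScheme", "SpeciesTraitTable"]


@dataclass(frozen=True)
class Trait:
    """One categorical trait: a name, its ordered state labels, and whether
    the states are ordinal (rank-ordered, e.g. body-size classes)."""

    name: str
    states: tuple[str, ...]
    ordinal: bool = False

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ValueError(f"trait {self.name!r} needs at least one state")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"trait {self.name!r} has duplicate state labels")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise ValueError(
                f"unknown state {label!r} for trait {self.name!r}; "
                f"declared states: {list(self.states)}"
            ) from None


@dataclass(frozen=True)
class TraitScheme:
    """Ordered collection of traits defining the functional-trait space."""

    traits: tuple[Trait, ...]

    def __post_init__(self) -> None:
        if len(self.traits) < 1:
            raise ValueError("scheme needs at least one trait")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names in scheme")

    @classmethod
    def from_states(
        cls,
        states: dict[str, Sequence[str]],
        ordinal: Iterable[str] = (),
    ) -> "TraitScheme":
        ordinal = set(ordinal)
        return cls(
            tuple(
                Trait(name, tuple(labels), ordinal=name in ordinal)
                for name, labels in states.items()
            )
        )

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    @property
    def states_per_trait(self) -> np.ndarray:
        return np.array([t.n_states for t in self.traits], dtype=int)

    def __getitem__(self, name: str) -> Trait:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass
class SpeciesTraitTable:
    """Per-species trait states, stored as integer state indices.

    ``states`` is an ``(S, V)`` integer matrix; ``states[i, v]`` indexes into
    ``scheme.traits[v].states``.
    """

    scheme: TraitScheme
    species_ids: list[str]
    states: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        S, V = self.states.shape
        if S != len(self.species_ids):
            raise ValueError("species_ids length does not match state matrix")
        if S < 1:
            raise ValueError("trait table must contain at least one species")
        if V != self.scheme.n_traits:
            raise ValueError(
                f"state matrix has {V} columns but scheme declares "
                f"{self.scheme.n_traits} traits"
            )
        if len(set(self.species_ids)) != S:
            dupes = pd.Index(self.species_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate species ids: {dupes}")
        upper = self.scheme.states_per_trait
        if (self.states < 0).any() or (self.states >= upper).any():
            raise ValueError("state index out of range for its trait")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scheme: TraitScheme) -> "SpeciesTraitTable":
        """Build a table from a labelled DataFrame (``species_id`` + one
        column per trait, holding state labels)."""
        if "species_id" not in frame.columns:
            raise KeyError("missing required column 'species_id'")
        missing = [t.name for t in scheme.traits if t.name not in frame.columns]
        if missing:
            raise KeyError(f"missing trait columns: {missing}")
        species = frame["species_id"].astype(str).tolist()
        S = len(species)
        states = np.empty((S, scheme.n_traits), dtype=np.int64)
        for v, trait in enumerate(scheme.traits):
            col = frame[trait.name].astype(str).to_numpy()
            lookup = {label: i for i, label in enumerate(trait.states)}
            for i, label in enumerate(col):
                if label not in lookup:
                    raise ValueError(
                        f"species {species[i]!r}: unknown state {label!r} "
                        f"for trait {trait.name!r}"
                    )
                states[i, v] = lookup[label]
        return cls(scheme=scheme, species_ids=species, states=states)

    def to_frame(self) -> pd.DataFrame:
        data = {"species_id": self.species_ids}
        for v, trait in enumerate(self.scheme.traits):
            labels = np.asarray(trait.states, dtype=object)
            data[trait.name] = labels[self.states[:, v]]
        return pd.DataFrame(data)

    @property
    def n_species(self) -> int:
        return self.states.shape[0]

    def subset(self, index: np.ndarray) -> "SpeciesTraitTable":
        """Row subset by boolean mask or integer index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpeciesTraitTable(
            scheme=self.scheme,
            species_ids=[self.species_ids[i] for i in index],
            states=self.states[index],
        )
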