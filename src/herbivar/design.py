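"""Descriptions of the reciprocal-transplant design and generative parameters.

The default layout mirrors the goldenrod study that motivates this package:
two source populations from the plant's native range (US) and three from the
introduced range (Japan), ten clonal genotypes per population, five common
gardens (two US, three Japanese), and five ramets of every genotype in every
garden.  Two herbivory traits are tracked per plant: a weighted lace-bug
damage score and a count of leaves damaged by other herbivores.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from ._linalg import require_psd

US = "US"
JP = "JP"
COUNTRIES = (US, JP)

TRAITS = ("lace_bug", "other")

#: (garden_id, garden_country) for the study's five common gardens.
DEFAULT_GARDENS = (
    ("Minnesota", US),
    ("Kansas", US),
    ("Yamagata", JP),
    ("Shiga", JP),
    ("Saga", JP),
)

#: (population_id, origin_country) for the five source populations.
DEFAULT_POPULATIONS = (
    ("Minnesota", US),
    ("Kansas", US),
    ("Saga", JP),
    ("Shiga", JP),
    ("Yamagata", JP),
)


def _check_country(label: str, what: str) -> str:
    if label not in COUNTRIES:
        raise ValueError(f"{what} country must be one of {COUNTRIES}, got {label!r}")
    return label


@dataclass(frozen=True)
class DesignSpec:
    """Layout of a clonal reciprocal-transplant experiment."""

    populations: tuple[tuple[str, str], ...] = DEFAULT_POPULATIONS
    genotypes_per_population: int = 10
    gardens: tuple[tuple[str, str], ...] = DEFAULT_GARDENS
    ramets_per_genotype_per_garden: int = 5
    #: (mean, dispersion) of the negative-binomial total-leaf-count model.
    leaf_count_model: tuple[float, float] = (40.0, 8.0)

    def __post_init__(self):
        if self.genotypes_per_population < 1:
            raise ValueError("genotypes_per_population must be >= 1")
        if self.ramets_per_genotype_per_garden < 1:
            raise ValueError("ramets_per_genotype_per_garden must be >= 1")
        pop_ids = [p for p, _ in self.populations]
        if len(set(pop_ids)) != len(pop_ids):
            raise ValueError("population IDs must be unique")
        garden_ids = [g for g, _ in self.gardens]
        if len(set(garden_ids)) != len(garden_ids):
            raise ValueError("garden IDs must be unique")
        if not self.populations:
            raise ValueError("at least one population required")
        if not self.gardens:
            raise ValueError("at least one garden required")
        for _, c in self.populations:
            _check_country(c, "population origin")
        for _, c in self.gardens:
            _check_country(c, "garden")
        mean, disp = self.leaf_count_model
        if mean <= 0 or disp <= 0:
            raise ValueError("leaf_count_model mean and dispersion must be positive")

    @property
    def n_plants(self) -> int:
        return (
            len(self.populations)
            * self.genotypes_per_population
            * len(self.gardens)
            * self.ramets_per_genotype_per_garden
        )

    def genotype_ids(self) -> list[str]:
        return [
            f"{pop}-g{j:02d}"
            for pop, _ in self.populations
            for j in range(1, self.genotypes_per_population + 1)
        ]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignSpec":
        d = dict(d)
        for key in ("populations", "gardens"):
            if key in d:
                d[key] = tuple(tuple(x) for x in d[key])
        if "leaf_count_model" in d:
            d["leaf_count_model"] = tuple(d["leaf_count_model"])
        return cls(**d)


def _matrix_field(default):
    return field(default_factory=lambda: np.array(default, dtype=float))


@dataclass
class TrueParams:
    """Latent-scale generative parameters for the synthetic experiment.

    All covariance matrices are 2x2 over the trait pair
    (lace-bug damage score, other-herbivore damaged leaves) on the log-link
    scale of the Poisson observation model.
    """

    G_lat: np.ndarray = _matrix_field([[0.3, -0.15], [-0.15, 0.3]])
    P_pop: np.ndarray = _matrix_field([[0.05, 0.0], [0.0, 0.05]])
    Q_garden: np.ndarray = _matrix_field([[0.1, 0.0], [0.0, 0.1]])
    R_lat: np.ndarray = _matrix_field([[0.2, 0.0], [0.0, 0.2]])
    intercepts: np.ndarray = field(default_factory=lambda: np.array([-1.5, -2.5]))
    offset_coefficient: float = 1.0
    category_weights: tuple[float, float, float, float] = (0.0, 1.0, 2.0, 3.0)
    #: probabilities of the three damaged levels (b, c, d) used when
    #: decomposing a lace-bug score into per-level leaf counts.
    level_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    #: optional garden-country-specific genetic covariances (environmentally
    #: triggered G); keys are country codes, values 2x2 PSD matrices.
    env_G: Mapping[str, np.ndarray] | None = None
    #: optional origin-country-specific genetic covariances.
    origin_G: Mapping[str, np.ndarray] | None = None

    def __post_init__(self):
        self.G_lat = require_psd(self.G_lat, "G_lat")
        self.P_pop = require_psd(self.P_pop, "P_pop")
        self.Q_garden = require_psd(self.Q_garden, "Q_garden")
        self.R_lat = require_psd(self.R_lat, "R_lat")
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.intercepts.shape != (2,):
            raise ValueError("intercepts must be length-2")
        w = tuple(float(x) for x in self.category_weights)
        if len(w) != 4:
            raise ValueError("category_weights must have length 4")
        if any(x < 0 for x in w):
            raise ValueError("category_weights must be non-negative")
        if any(w[i] > w[i + 1] for i in range(3)):
            raise ValueError("category_weights must be monotone non-decreasing")
        self.category_weights = w
        p = np.asarray(self.level_probs, dtype=float)
        if p.shape != (3,) or (p < 0).any() or p.sum() <= 0:
            raise ValueError("level_probs must be 3 non-negative numbers with positive sum")
        self.level_probs = tuple(float(x) for x in p / p.sum())
        for attr in ("env_G", "origin_G"):
            mapping = getattr(self, attr)
            if mapping is not None:
                setattr(
                    self,
                    attr,
                    {
                        _check_country(c, attr): require_psd(M, f"{attr}[{c}]")
                        for c, M in mapping.items()
                    },
                )

    def genetic_cov_for(self, origin_country: str, garden_country: str) -> np.ndarray:
        """Genetic covariance in effect for a genotype/garden combination."""
        if self.env_G is not None and garden_country in self.env_G:
            return self.env_G[garden_country]
        if self.origin_G is not None and origin_country in self.origin_G:
            return self.origin_G[origin_country]
        return self.G_lat

    def to_dict(self) -> dict:
        d = {
            "G_lat": self.G_lat.tolist(),
            "P_pop": self.P_pop.tolist(),
            "Q_garden": self.Q_garden.tolist(),
            "R_lat": self.R_lat.tolist(),
            "intercepts": self.intercepts.tolist(),
            "offset_coefficient": float(self.offset_coefficient),
            "category_weights": [float(x) for x in self.category_weights],
            "level_probs": [float(x) for x in self.level_probs],
        }
        for attr in ("env_G", "origin_G"):
            mapping = getattr(self, attr)
            d[attr] = None if mapping is None else {c: np.asarray(M).tolist() for c, M in mapping.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrueParams":
        d = dict(d)
        for key in ("G_lat", "P_pop", "Q_garden", "R_lat", "intercepts"):
            if key in d and d[key] is not None:
                d[key] = np.asarray(d[key], dtype=float)
        for key in ("category_weights", "level_probs"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("env_G", "origin_G"):
            if d.get(key) is not None:
                d[key] = {c: np.asarray(M, dtype=float) for c, M in d[key].items()}
        return cls(**d)
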