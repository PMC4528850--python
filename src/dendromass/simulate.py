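"""Seeded synthetic tree-dataset generator.

Emulates the structure of destructive biomass samples from young
mixed-species restoration plantings: a right-skewed diameter distribution,
height coupled allometrically to diameter with substantial between-tree
scatter (many species at a given size class), auxiliary crown and density
variables positively correlated with size or species, and biomass following
a log-linear allometry with multiplicative lognormal error,

    w = exp(a + b*ln(dbh) + c*ln(ht) + eps),   eps ~ N(0, sigma^2).

With ``n_species > 1`` the allometric parameters (a, b, c) vary between
species ("heterogeneity mode"): species s receives offsets
``spread * u_s`` with ``u_s`` evenly spaced on [-1/2, 1/2], so for two
species the parameter differs by exactly the spread.  Species also shift the
basic wood density, giving nearest-neighbor methods a feature through which
the regime is (weakly) identifiable — as with real species-specific wood
densities.

Every draw is reproducible from the integer seed (PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import TreeDataset

#: defaults of the biomass law on the ln scale (young Atlantic-Forest
#: restoration allometry: w in kg, dbh in cm, ht in m)
DEFAULT_A = -1.390796
DEFAULT_B = 1.051491
DEFAULT_C = 1.084280


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset draw.

    sigma is the SD of the multiplicative (ln-scale) biomass error.  The
    spreads are total between-species ranges of the respective allometric
    parameter; they only act when ``n_species > 1``.
    """

    n: int = 180
    a: float = DEFAULT_A
    b: float = DEFAULT_B
    c: float = DEFAULT_C
    sigma: float = 0.3
    dbh_min: float = 1.0
    dbh_max: float = 25.0
    ht_coef: float = 1.9         # ht = ht_coef * dbh**ht_exp * lognormal noise
    ht_exp: float = 0.55
    ht_sigma: float = 0.4        # ln-scale height scatter (species mixture)
    n_species: int = 1
    spread_a: float = 0.0
    spread_b: float = 0.5
    spread_c: float = 0.0
    db_species_shift: float = 0.10   # density offset per unit u_s
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not 0 < self.dbh_min < self.dbh_max:
            raise ValueError("need 0 < dbh_min < dbh_max")
        if self.n_species < 1:
            raise ValueError(f"n_species must be >= 1, got {self.n_species}")


def _species_offsets(n_species: int) -> np.ndarray:
    """Evenly spaced offsets u_s on [-1/2, 1/2]; 0 for a single species."""
    if n_species == 1:
        return np.zeros(1)
    return np.linspace(-0.5, 0.5, n_species)


def generate(spec: SyntheticSpec | None = None, **overrides) -> TreeDataset:
    """Draw one synthetic tree dataset.

    Construction, in order (all from one seeded PCG64 stream):

    * ``dbh = dbh_min * (dbh_max/dbh_min)**Beta(1, 1.6)`` — a bounded
      reverse-J diameter distribution (many small stems, few large ones),
      the classic shape of young uneven stands;
    * ``ht = ht_coef * dbh**ht_exp * exp(N(0, ht_sigma))``;
    * ``dm = 0.45 * dbh**0.6 * exp(N(0, 0.15))`` (crown diameter, m);
    * ``hc = ht * Beta(2, 4)`` (crown base strictly inside (0, ht));
    * ``db`` lognormal around a species-shifted mean ≈0.45 g/cm³, clipped to
      [0.2, 0.9]; ``da = db * (1 + U(0.15, 0.35))`` so db < da always;
    * ``w`` from the log-linear law with the species' (a, b, c) and
      lognormal error exp(N(0, sigma)).

    Returns a validated raw-scale :class:`TreeDataset` with a ``species``
    column.
    """
    spec = replace(spec, **overrides) if spec is not None else SyntheticSpec(**overrides)
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    species = rng.integers(0, spec.n_species, size=n)
    u = _species_offsets(spec.n_species)[species]
    a_i = spec.a + spec.spread_a * u
    b_i = spec.b + spec.spread_b * u
    c_i = spec.c + spec.spread_c * u

    dbh = spec.dbh_min * (spec.dbh_max / spec.dbh_min) ** rng.beta(1.0, 1.6, size=n)
    ht = spec.ht_coef * dbh**spec.ht_exp * np.exp(rng.normal(0.0, spec.ht_sigma, size=n))
    dm = 0.45 * dbh**0.6 * np.exp(rng.normal(0.0, 0.15, size=n))
    hc = ht * rng.beta(2.0, 4.0, size=n)
    db = np.clip(
        (0.45 + spec.db_species_shift * u) * np.exp(rng.normal(0.0, 0.08, size=n)),
        0.2, 0.9)
    da = db * (1.0 + rng.uniform(0.15, 0.35, size=n))
    eps = rng.normal(0.0, spec.sigma, size=n) if spec.sigma > 0 else np.zeros(n)
    w = np.exp(a_i + b_i * np.log(dbh) + c_i * np.log(ht) + eps)

    df = pd.DataFrame({
        "record_id": np.arange(n),
        "dbh": dbh, "dm": dm, "ht": ht, "hc": hc, "da": da, "db": db, "w": w,
        "species": [f"sp{s:02d}" for s in species],
    })
    ds = TreeDataset(records=df, transform_state="raw",
                     provenance=f"synthetic(seed={spec.seed}, n={n}, "
                                f"n_species={spec.n_species}, sigma={spec.sigma})")
    return ds.validate()


def generate_two_regime(spec: SyntheticSpec | None = None, **overrides) -> TreeDataset:
    """Heterogeneous-forest draw: >= 2 species with spread allometric params.

    A convenience front for :func:`generate` that defaults ``n_species`` to 2
    (the minimal heterogeneous forest) and requires it to be at least 2.
    Species are assigned uniformly at random; each species' (a, b, c) is
    offset by its share of the configured spreads.
    """
    spec = replace(spec, **overrides) if spec is not None else SyntheticSpec(**overrides)
    if spec.n_species < 2:
        spec = replace(spec, n_species=2)
    return generate(spec)
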