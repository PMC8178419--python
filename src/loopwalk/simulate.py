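"""Synthetic loop-mutagenesis screens with known ground truth.

The generator emulates a saturation-mutagenesis screen of three consecutive
loop positions: residue triples are drawn uniformly from the 20^3 space, a
sparse linear model on the standardized 39-dimensional physicochemical
encoding produces a latent stability score, and the retained-activity
fraction after heat treatment is a logistic function of that score plus
Gaussian measurement noise.  The untreated-activity channel is drawn
log-normally around a baseline with a configurable coefficient of
variation (default 15%, typical assay error for lysate activities), and
residual activity is the product of the two.

Defaults mirror the screen the analysis is designed for: 214 distinct
mutants, five nonzero generator weights concentrated on position 1 (the
dominant position in real loop screens is strongly asymmetric), and noise
standard deviation of 0.25x the latent signal's standard deviation.

Ground truth (noiseless latent scores and the labels they imply) is kept
alongside the records so recovery of the generator by the discrimination
cascade can be measured exactly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cascade import StratificationConfig, stratify_by_tertiles
from .descriptors import (
    ALPHABET,
    DescriptorTable,
    apply_scaler,
    encode_library,
    fit_scaler,
)
from .screening import MutantRecord, write_screen_table

__all__ = [
    "GenerativeConfig",
    "SyntheticScreen",
    "default_true_weights",
    "sample_variant_library",
    "simulate_thermostability",
    "generate_screen",
    "ground_truth_labels",
]

#: Default sparse generator weights, by position-major feature name.
#: Three nonzeros in the position-1 block and one in each other block; the
#: sign pattern (acid-friendly, aromatics-averse at position 1) mirrors the
#: asymmetry real loop screens show.
DEFAULT_WEIGHT_PATTERN: dict[str, float] = {
    "p1:isoelectric_point": -1.0,
    "p1:sidechain_stability": -1.3,
    "p1:polarity": 0.9,
    "p2:sidechain_interaction": 0.5,
    "p3:atom_atom_potential": -0.8,
}


def default_true_weights(table: DescriptorTable | None = None) -> np.ndarray:
    """The default 39-vector of generator weights (position-major)."""
    table = table if table is not None else DescriptorTable.paper_set()
    names = [f"p{k}:{d}" for k in (1, 2, 3) for d in table.descriptor_ids]
    w = np.zeros(len(names))
    for name, value in DEFAULT_WEIGHT_PATTERN.items():
        w[names.index(name)] = value
    return w


@dataclass(frozen=True)
class GenerativeConfig:
    """Study conditions for one synthetic screen.

    ``noise_sd`` is the standard deviation of Gaussian noise added to the
    latent stability score; ``None`` sets it to 0.25x the standard
    deviation of the noiseless latent over the sampled library.
    ``baseline_activity_mean`` / ``baseline_activity_cv`` parameterise the
    log-normal untreated-activity channel (U/mL).
    """

    n_mutants: int = 214
    true_weights: np.ndarray | None = None
    intercept: float = -1.0
    noise_sd: float | None = None
    baseline_activity_mean: float = 1000.0
    baseline_activity_cv: float = 0.15
    wildtype_triple: str = "PLV"
    unique: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mutants < 1:
            raise ValueError("n_mutants must be >= 1")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_activity_mean <= 0 or self.baseline_activity_cv < 0:
            raise ValueError("baseline activity mean must be > 0 and cv >= 0")
        if len(self.wildtype_triple) != 3 or any(
            c not in ALPHABET for c in self.wildtype_triple
        ):
            raise ValueError(f"invalid wild-type triple {self.wildtype_triple!r}")


@dataclass(frozen=True)
class SyntheticScreen:
    """Generated records plus aligned per-record ground truth.

    ``records`` holds the mutant records; ``wildtype`` the flagged
    wild-type record.  ``truth`` has one row per record (wild type
    included, flagged) with the noiseless latent score, the noisy latent
    actually used, and the retained fraction.
    """

    records: list[MutantRecord]
    wildtype: MutantRecord
    truth: pd.DataFrame
    config: GenerativeConfig

    def to_tsv(self, path: str | Path) -> None:
        write_screen_table(self.records, self.wildtype, path)

    def truth_to_json(self, path: str | Path) -> None:
        payload = {
            "noise_sd": float(self.truth.attrs["noise_sd"]),
            "intercept": float(self.config.intercept),
            "seed": int(self.config.seed),
            "records": self.truth.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _index_to_triple(i: int, alphabet: str) -> str:
    b = len(alphabet)
    return alphabet[i // (b * b)] + alphabet[(i // b) % b] + alphabet[i % b]


def sample_variant_library(
    n: int,
    seed: int | np.random.Generator = 0,
    unique: bool = True,
    alphabet: str = ALPHABET,
) -> list[str]:
    """Draw residue triples uniformly from the combinatorial space.

    With ``unique`` the draw is without replacement (n must not exceed the
    space size, 8000 for the 20-letter alphabet).  Deterministic for a
    fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    space = len(alphabet) ** 3
    if unique and n > space:
        raise ValueError(f"cannot draw {n} unique triples from a space of {space}")
    idx = rng.choice(space, size=n, replace=not unique)
    return [_index_to_triple(int(i), alphabet) for i in idx]


_SCALER_CACHE: dict[int, tuple[DescriptorTable, object]] = {}


def _full_space_scaler(table: DescriptorTable):
    """Scaler over the full 20^3 encoding; library-independent standardization.

    Cached per table object (the cache entry keeps the table alive so ids
    are not recycled).
    """
    key = id(table)
    hit = _SCALER_CACHE.get(key)
    if hit is not None and hit[0] is table:
        return hit[1]
    full = encode_library(
        ["".join(t) for t in itertools.product(ALPHABET, repeat=3)], table
    )
    scaler = fit_scaler(full.to_numpy(float))
    _SCALER_CACHE[key] = (table, scaler)
    return scaler


def simulate_thermostability(
    triples: Sequence[str],
    config: GenerativeConfig,
    table: DescriptorTable | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticScreen:
    """Simulate the two activity channels for given triples.

    Latent score s = w . z + intercept + N(0, noise_sd) on features
    standardized over the full 20^3 space; retained fraction =
    logistic(s), strictly inside (0, 1); untreated activity is log-normal
    around the baseline mean; residual activity = untreated x retained.
    The wild-type record is generated through the same channels and
    flagged.
    """
    table = table if table is not None else DescriptorTable.paper_set()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    w = (
        np.asarray(config.true_weights, float)
        if config.true_weights is not None
        else default_true_weights(table)
    )
    scaler = _full_space_scaler(table)
    all_triples = [config.wildtype_triple, *["".join(t) for t in triples]]
    Z = apply_scaler(encode_library(all_triples, table).to_numpy(float), scaler)
    if Z.shape[1] != w.shape[0]:
        raise ValueError(
            f"true_weights length {w.shape[0]} does not match {Z.shape[1]} features"
        )
    latent_true = Z @ w + config.intercept
    noise_sd = (
        config.noise_sd
        if config.noise_sd is not None
        else 0.25 * float(np.std(latent_true[1:]))  # mutants only
    )
    latent_noisy = latent_true + rng.normal(0.0, noise_sd, size=latent_true.shape)
    retained = 1.0 / (1.0 + np.exp(-latent_noisy))

    cv = config.baseline_activity_cv
    sigma = np.sqrt(np.log1p(cv * cv))
    mu = np.log(config.baseline_activity_mean) - sigma * sigma / 2.0
    activity = np.exp(rng.normal(mu, sigma, size=latent_true.shape)) if cv > 0 else np.full(
        latent_true.shape, config.baseline_activity_mean
    )
    residual = activity * retained

    ids = ["WT"] + [f"m{i:04d}" for i in range(1, len(all_triples))]
    records = [
        MutantRecord(vid, t, float(a), float(r))
        for vid, t, a, r in zip(ids, all_triples, activity, residual)
    ]
    truth = pd.DataFrame(
        {
            "variant_id": ids,
            "triple": all_triples,
            "latent_true": latent_true,
            "latent_noisy": latent_noisy,
            "retained_fraction": retained,
            "is_wildtype": [True] + [False] * (len(all_triples) - 1),
        }
    )
    truth.attrs["noise_sd"] = noise_sd
    return SyntheticScreen(
        records=records[1:], wildtype=records[0], truth=truth, config=config
    )


def generate_screen(
    config: GenerativeConfig | None = None, table: DescriptorTable | None = None
) -> SyntheticScreen:
    """Sample a library and simulate its screen (independent seeded streams)."""
    config = config or GenerativeConfig()
    ss = np.random.SeedSequence(config.seed)
    s_lib, s_sim = ss.spawn(2)
    triples = sample_variant_library(
        config.n_mutants,
        seed=np.random.default_rng(s_lib),
        unique=config.unique,
    )
    return simulate_thermostability(
        triples, config, table, rng=np.random.default_rng(s_sim)
    )


def ground_truth_labels(
    screen: SyntheticScreen, config: StratificationConfig | None = None
) -> np.ndarray:
    """Oracle tertile labels from the noiseless latent scores (mutants only)."""
    truth = screen.truth
    if "latent_true" not in truth.columns:
        raise ValueError("screen carries no ground truth")
    mutants = truth[~truth["is_wildtype"]]
    return stratify_by_tertiles(mutants["latent_true"].to_numpy(), config)
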