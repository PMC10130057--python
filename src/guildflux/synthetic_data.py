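"""Seeded generators for every pipeline input, with known ground truth.

Each generator draws from its own ``numpy.random.default_rng(seed)``
substream, so identical arguments plus seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .diversity import AbundanceProfile, shannon
from .expression import CDSRecord
from .stoichiometry import (
    GUILD_ORDER,
    N_MOLAR_MASS,
    PARTITION_SPECIES,
    MeasurementSeries,
    ReactorConfig,
    build_stoich_matrix,
    guild_reactions,
)

__all__ = [
    "GenomeSpec",
    "gen_reactor_series",
    "gen_expression_counts",
    "gen_abundance_profiles",
]


def _as_extent_vector(extents) -> np.ndarray:
    if isinstance(extents, Mapping):
        vec = np.array([float(extents.get(g, 0.0)) for g in GUILD_ORDER])
    else:
        vec = np.asarray(extents, dtype=float)
        if vec.shape != (3,):
            raise ValueError("extents must have three entries (guild order)")
    if np.any(vec < 0):
        raise ValueError("extents must be >= 0")
    return vec


def gen_reactor_series(
    extents,
    noise_cv: float,
    n_samples: int,
    config: ReactorConfig,
    seed: int,
) -> Tuple[MeasurementSeries, Dict]:
    """Steady-state effluent series generated by known guild extents.

    The expected effluent is ``influent + HRT * S e`` on the mg N basis
    (consumption negative); each sample applies multiplicative Gaussian
    noise of coefficient of variation ``noise_cv``, with negative draws
    clamped to 0 and recorded in the ground truth.

    Returns the tidy series plus a ground-truth dict with the extents,
    expected effluent and clamp bookkeeping.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    e = _as_extent_vector(extents)
    rng = np.random.default_rng(seed)
    registry = guild_reactions()
    S = build_stoich_matrix([registry[g] for g in GUILD_ORDER], PARTITION_SPECIES)
    rate_mg = N_MOLAR_MASS * (S @ e)  # mg N/L/d, consumption negative
    expected = {
        sp: config.influent.get(sp, 0.0) + config.hrt_days * rate_mg[i]
        for i, sp in enumerate(PARTITION_SPECIES)
    }
    for sp, v in expected.items():
        if v < -1e-9:
            raise ValueError(
                f"extents over-consume {sp}: expected effluent {v:.3f} mg N/L < 0"
            )

    rows = []
    clamped: List[Tuple[float, str]] = []
    times = np.arange(1, n_samples + 1, dtype=float)
    for t in times:
        for sp in PARTITION_SPECIES:
            mu = max(expected[sp], 0.0)
            value = mu * (1.0 + noise_cv * rng.standard_normal()) if noise_cv > 0 else mu
            if value < 0:
                clamped.append((t, sp))
                value = 0.0
            rows.append((t, sp, value, "mg_N/L"))
    series = MeasurementSeries(
        pd.DataFrame(rows, columns=["time_d", "species", "value", "unit"])
    )
    truth = {
        "extents": {g: float(v) for g, v in zip(GUILD_ORDER, e)},
        "expected_effluent": expected,
        "rate_mg_n": {sp: float(rate_mg[i]) for i, sp in enumerate(PARTITION_SPECIES)},
        "clamped": clamped,
        "seed": seed,
    }
    return series, truth


@dataclass(frozen=True)
class GenomeSpec:
    """Size and naming of one synthetic genome's CDS complement."""

    genome_id: str
    n_cds: int
    min_len: int = 300
    max_len: int = 3000


def gen_expression_counts(
    genome_catalog: Sequence[GenomeSpec] | Mapping[str, int],
    fractions: Mapping[str, float],
    total_reads: int,
    seed: int,
    within_genome_sigma: float = 1.0,
) -> Tuple[List[CDSRecord], Dict[str, int], Dict]:
    """Multinomial per-CDS read counts from known per-genome TPM fractions.

    Per-CDS sampling probability is proportional to
    ``fraction(genome) * weight(cds) * length(cds)`` with log-normal
    within-genome weights normalized to 1 per genome, so the expected TPM
    share of each genome equals its target fraction exactly.

    Returns (CDS records, counts by cds_id, ground truth).  The ground
    truth carries the expected (non-integer) counts so exact-recovery tests
    can bypass sampling noise.
    """
    if isinstance(genome_catalog, Mapping):
        genome_catalog = [GenomeSpec(g, n) for g, n in genome_catalog.items()]
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    frac = {g.genome_id: float(fractions[g.genome_id]) for g in genome_catalog}
    total_frac = sum(frac.values())
    if not np.isclose(total_frac, 1.0, atol=1e-9):
        raise ValueError(f"fractions must sum to 1 (got {total_frac})")

    rng = np.random.default_rng(seed)
    records: List[CDSRecord] = []
    probs: List[float] = []
    weights: Dict[str, float] = {}
    for spec in genome_catalog:
        lengths = rng.integers(spec.min_len, spec.max_len + 1, size=spec.n_cds)
        w = rng.lognormal(mean=0.0, sigma=within_genome_sigma, size=spec.n_cds)
        w /= w.sum()
        strands = rng.choice(["+", "-"], size=spec.n_cds)
        for i in range(spec.n_cds):
            cds_id = f"{spec.genome_id}_cds{i:04d}"
            records.append(
                CDSRecord(
                    cds_id=cds_id,
                    genome_id=spec.genome_id,
                    gene_symbol=f"gene_{cds_id}",
                    complex_id="",
                    length=int(lengths[i]),
                    strand=str(strands[i]),
                )
            )
            weights[cds_id] = float(w[i])
            probs.append(frac[spec.genome_id] * w[i] * lengths[i])

    probs_arr = np.asarray(probs)
    probs_arr = probs_arr / probs_arr.sum()
    if total_reads > 0:
        draws = rng.multinomial(total_reads, probs_arr)
    else:
        draws = np.zeros(len(records), dtype=int)
    counts = {rec.cds_id: int(c) for rec, c in zip(records, draws)}
    truth = {
        "fractions": frac,
        "weights": weights,
        "expected_counts": {
            rec.cds_id: float(total_reads * p) for rec, p in zip(records, probs_arr)
        },
        "seed": seed,
    }
    return records, counts, truth


def gen_abundance_profiles(
    n_samples: int,
    n_categories: int,
    concentration: float,
    seed: int,
) -> Tuple[List[AbundanceProfile], Dict]:
    """Dirichlet-distributed abundance profiles with evenness control.

    ``concentration`` is the symmetric Dirichlet parameter: large values
    give near-uniform profiles (H -> ln n), small values give skewed ones.
    Ground truth reports the Shannon index of the empirical mean profile
    and the per-sample values.
    """
    if n_samples < 1 or n_categories < 1:
        raise ValueError("n_samples and n_categories must be >= 1")
    if not concentration > 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    labels = [f"otu{i:03d}" for i in range(n_categories)]
    alpha = np.full(n_categories, concentration)
    draws = rng.dirichlet(alpha, size=n_samples)
    profiles = [AbundanceProfile(labels, row) for row in draws]
    mean_profile = AbundanceProfile(labels, draws.mean(axis=0))
    truth = {
        "concentration": concentration,
        "h_mean_profile": shannon(mean_profile),
        "h_samples": [shannon(p) for p in profiles],
        "seed": seed,
    }
    return profiles, truth
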