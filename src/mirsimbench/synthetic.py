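"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The generators emulate the three ingredients of a miRNA-disease
association study: families of ~22-nt miRNA sequences with controlled
divergence (one random ancestor per family, independent per-position
substitutions per member), expression matrices with block correlation
(family-shared latent profile plus independent noise), and association
tables in which diseases planted on one family member propagate to
co-members with probability ``p_within`` and to unrelated miRNAs with
probability ``p_background``. A label-permutation null destroys the
similarity-association coupling while conserving per-disease counts.

All generators are pure functions of config + seed. The global seed is
split into fixed per-component streams, so adding a generator never
perturbs another's output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InputError
from .mbsi import AssociationTable
from .similarity import ExpressionMatrix, SequenceSet

_RNA_ALPHABET = np.array(list("ACGU"))

# Fixed spawn keys, one per generator stream.
_STREAM_SEQUENCES = 0
_STREAM_EXPRESSION = 1
_STREAM_ASSOCIATIONS = 2
_STREAM_PERMUTATION = 3


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the planted synthetic benchmark.

    Defaults are the benchmark conditions used throughout the test
    suite: 6 families of 10 miRNAs, 22-nt sequences mutated at 10% per
    position, 24 expression conditions, 20 diseases shared within
    families with probability 0.8 against a 0.05 background.
    """

    n_families: int = 6
    members_per_family: int = 10
    seq_length: int = 22
    mutation_rate: float = 0.1
    n_conditions: int = 24
    within_block_corr: float = 0.6
    noise_sd: float = 1.0
    n_diseases: int = 20
    p_within: float = 0.8
    p_background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_families, self.members_per_family, self.seq_length,
               self.n_conditions, self.n_diseases) < 1:
            raise ConfigurationError("all counts must be positive")
        if not (0 <= self.mutation_rate < 1):
            raise ConfigurationError("mutation_rate must be in [0, 1)")
        if not (0 <= self.within_block_corr < 1):
            raise ConfigurationError("within_block_corr must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        for name in ("p_within", "p_background"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.p_within < self.p_background:
            raise ConfigurationError(
                "p_within must be >= p_background (equal only for nulls)"
            )
        if self.within_block_corr == 0 and self.noise_sd == 0:
            raise ConfigurationError(
                "within_block_corr=0 with noise_sd=0 yields constant rows"
            )

    @property
    def n_mirnas(self) -> int:
        return self.n_families * self.members_per_family

    def mirna_ids(self) -> tuple[str, ...]:
        """IDs encoding family membership: ``fam{f:02d}-mir{m:02d}``."""
        return tuple(
            f"fam{f:02d}-mir{m:02d}"
            for f in range(self.n_families)
            for m in range(self.members_per_family)
        )

    def family_of(self, mirna_id: str) -> int:
        return int(mirna_id.split("-")[0][3:])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg_seed, spawn_key=(stream,))
    )


def gen_sequences(cfg: SyntheticConfig) -> SequenceSet:
    """Family-structured RNA sequences: ancestor + per-member substitutions.

    Each family draws one ancestor uniformly over {A,C,G,U}; each member
    independently substitutes every position with probability
    ``mutation_rate``, drawing uniformly from the three alternative bases.
    """
    rng = _rng(cfg.seed, _STREAM_SEQUENCES)
    seqs: list[str] = []
    for _ in range(cfg.n_families):
        ancestor = rng.integers(0, 4, size=cfg.seq_length)
        for _ in range(cfg.members_per_family):
            member = ancestor.copy()
            mutate = rng.random(cfg.seq_length) < cfg.mutation_rate
            # draw an offset 1..3 so the substituted base always differs
            offsets = rng.integers(1, 4, size=cfg.seq_length)
            member[mutate] = (member[mutate] + offsets[mutate]) % 4
            seqs.append("".join(_RNA_ALPHABET[member]))
    return SequenceSet(ids=cfg.mirna_ids(), sequences=tuple(seqs))


def gen_expression(cfg: SyntheticConfig) -> ExpressionMatrix:
    """Block-correlated nonnegative expression matrix.

    Each family shares a standard-normal latent profile; member rows are
    ``sqrt(rho) * latent + sqrt(1 - rho) * noise_sd * eps`` with rho =
    ``within_block_corr``, so at the default ``noise_sd`` of 1 the
    expected within-family Pearson correlation is rho, and ``noise_sd=0``
    recovers perfectly correlated rows. The whole matrix is shifted to be
    nonnegative (a common shift leaves all correlations unchanged).
    """
    if cfg.n_conditions < 3:
        raise ConfigurationError("need at least 3 conditions for correlations")
    rng = _rng(cfg.seed, _STREAM_EXPRESSION)
    rho = cfg.within_block_corr
    rows = []
    for _ in range(cfg.n_families):
        latent = rng.standard_normal(cfg.n_conditions)
        for _ in range(cfg.members_per_family):
            eps = rng.standard_normal(cfg.n_conditions)
            rows.append(
                np.sqrt(rho) * latent + np.sqrt(1 - rho) * cfg.noise_sd * eps
            )
    values = np.vstack(rows)
    lo = values.min()
    if lo < 0:
        values = values - lo
    return ExpressionMatrix(
        ids=cfg.mirna_ids(),
        condition_labels=tuple(f"cond{c:02d}" for c in range(cfg.n_conditions)),
        values=values,
    )


def gen_associations(
    cfg: SyntheticConfig, ids: Sequence[str] | None = None
) -> AssociationTable:
    """Plant disease associations preferentially within families.

    Every disease is seeded on one uniformly drawn (family, member); the
    seed member is always associated, co-members join with ``p_within``,
    and every miRNA outside the family with ``p_background``.
    """
    ids = tuple(ids) if ids is not None else cfg.mirna_ids()
    if not ids:
        raise InputError("empty miRNA ID list")
    if len(ids) != cfg.n_mirnas:
        raise InputError(
            f"expected {cfg.n_mirnas} IDs partitioned into families, "
            f"got {len(ids)}"
        )
    rng = _rng(cfg.seed, _STREAM_ASSOCIATIONS)
    m = cfg.members_per_family
    disease_ids = tuple(f"disease{j:02d}" for j in range(cfg.n_diseases))
    pairs: set[tuple[str, str]] = set()
    for d in disease_ids:
        fam = int(rng.integers(0, cfg.n_families))
        member = int(rng.integers(0, m))
        draws = rng.random(len(ids))
        for idx, mirna in enumerate(ids):
            in_family = idx // m == fam
            if in_family and idx % m == member:
                pairs.add((mirna, d))
            elif in_family:
                if draws[idx] < cfg.p_within:
                    pairs.add((mirna, d))
            elif draws[idx] < cfg.p_background:
                pairs.add((mirna, d))
    return AssociationTable(mirna_ids=ids, disease_ids=disease_ids,
                            pairs=frozenset(pairs))


def permute_associations(
    tbl: AssociationTable,
    seed: int,
    permutation: Sequence[int] | None = None,
) -> AssociationTable:
    """Null model: randomly permute miRNA labels of the incidence rows.

    Per-disease association counts and the total pair count are
    conserved; only the coupling between miRNA identity (hence
    similarity) and associations is destroyed. An explicit
    ``permutation`` (indices into ``tbl.mirna_ids``) overrides the
    seed-drawn one.
    """
    if len(tbl) == 0:
        raise InputError("cannot permute an empty association table")
    n = len(tbl.mirna_ids)
    if permutation is None:
        perm = _rng(seed, _STREAM_PERMUTATION).permutation(n)
    else:
        perm = np.asarray(permutation, dtype=int)
        if sorted(perm.tolist()) != list(range(n)):
            raise InputError("permutation must be a permutation of 0..n-1")
    relabel = {tbl.mirna_ids[i]: tbl.mirna_ids[perm[i]] for i in range(n)}
    return AssociationTable(
        mirna_ids=tbl.mirna_ids,
        disease_ids=tbl.disease_ids,
        pairs=frozenset((relabel[m], d) for m, d in tbl.pairs),
    )


def write_synthetic_inputs(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit FASTA, expression TSV, association TSV and a config sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequences": outdir / "sequences.fasta",
        "expression": outdir / "expression.tsv",
        "associations": outdir / "associations.tsv",
        "config": outdir / "synthetic_config.json",
    }
    gen_sequences(cfg).to_fasta(paths["sequences"])
    gen_expression(cfg).write_tsv(paths["expression"])
    gen_associations(cfg).write_tsv(paths["associations"])
    paths["config"].write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
    return paths
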