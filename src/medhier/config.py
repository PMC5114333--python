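"""Run configuration: every tunable of the pipeline, with validation and JSON round-trip.

A single global seed is expanded deterministically into per-stage seeds via
:func:`stage_seed`, so a pipeline rerun with the same seed is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["RunConfig", "stage_seed", "ConfigError"]

# UMLS semantic groups whose concepts get the term-weight boost in the
# weighted term kernel: diseases, anatomy, symptoms and neoplasms carry the
# discriminative medical signal.
DEFAULT_BOOSTED_GROUPS = (
    "disease or syndrome",
    "body part, organ, or organ component",
    "sign or symptom",
    "neoplasm",
)


class ConfigError(ValueError):
    """Raised when a configuration value is out of its legal range."""


@dataclass
class RunConfig:
    """All pipeline tunables.

    Kernel fusion weights ``betas`` must lie on the probability simplex; the
    shrinkage threshold ``delta`` terminates node expansion when the
    inter-node relation of a trial bipartition exceeds it.
    """

    # --- kernels ---
    betas: tuple[float, float, float] = (0.6, 0.1, 0.3)
    concept_boost: float = 2.0
    boosted_groups: tuple[str, ...] = DEFAULT_BOOSTED_GROUPS
    phi3_polarity: str = "similarity"  # "similarity": 1 - JS/ln2; "divergence": raw JS

    # --- topic expansion ---
    k_min: int = 2
    k_max: int = 12
    alpha: float | None = None  # None -> 1/k
    eta: float = 0.01
    holdout_fraction: float = 0.1
    lda_max_iter: int = 25

    # --- shrinkage / assignment ---
    # identical halves give inter = 2 by construction; divisible nodes with
    # realistically shared vocabulary land near 1.3-1.6, homogeneous ones
    # near 1.9 -- delta sits between the regimes
    delta: float = 1.7
    min_node_size: int = 20
    shrinkage_sample: int = 100  # cap on members entering the O(n^2) relation averages

    # --- hierarchy ---
    depth_cap: int = 6
    first_layer_multilabel: bool = True
    negative_sample_size: int | None = None  # None -> match positive count

    # --- profiling ---
    phrase_candidates: int = 20  # top-k frequent noun phrases entering the vote
    labels_per_node: int = 5

    # --- retrieval ---
    lam: float = 9.0  # weight lam/(1+lam)=0.9 on initial scores (assumption 2)
    walk_tol: float = 1e-8
    walk_max_iter: int = 500
    rerank_pool: int = 150
    initial_score_kernel: str = "fused"  # or "phi1"

    # --- evaluation ---
    tuple_labels: int = 1  # labels per node entering tuple accuracy
    cohesiveness_labels: int = 0  # 0 -> all stored labels

    # --- misc ---
    keep_all_answers: bool = True
    stopwords: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.betas = tuple(float(b) for b in self.betas)
        if len(self.betas) != 3 or any(b < 0 for b in self.betas):
            raise ConfigError("betas must be three nonnegative weights")
        if abs(sum(self.betas) - 1.0) > 1e-9:
            raise ConfigError("betas must sum to 1")
        if self.concept_boost < 1:
            raise ConfigError("concept_boost must be >= 1")
        if not (0 < self.holdout_fraction < 1):
            raise ConfigError("holdout_fraction must lie in (0, 1)")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ConfigError("k range must satisfy 2 <= k_min <= k_max")
        if self.delta < 0:
            raise ConfigError("delta must be nonnegative")
        if self.min_node_size < 4:
            raise ConfigError("min_node_size must be >= 4")
        if self.lam <= 0:
            raise ConfigError("lam must be positive")
        if self.phi3_polarity not in ("similarity", "divergence"):
            raise ConfigError("phi3_polarity must be 'similarity' or 'divergence'")
        if self.initial_score_kernel not in ("fused", "phi1"):
            raise ConfigError("initial_score_kernel must be 'fused' or 'phi1'")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key in ("betas", "boosted_groups", "stopwords"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("betas", "boosted_groups", "stopwords"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    def replace(self, **kw: Any) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def stage_seed(seed: int, *labels: object) -> int:
    """Derive a per-stage seed (< 2**31) from a global seed and stage labels.

    Uses :class:`numpy.random.SeedSequence` entropy mixing so stages are
    statistically independent yet fully determined by ``seed``.  Labels are
    hashed with CRC32 (stable across processes, unlike ``hash``).
    """
    h = [zlib.crc32(str(lab).encode("utf-8")) for lab in labels]
    ss = np.random.SeedSequence([int(seed) % (2**32), *h])
    return int(ss.generate_state(1)[0] % (2**31))
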