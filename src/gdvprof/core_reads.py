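"""Core-read (CR) extraction.

A core read is a read whose target references all have near-identical local
sequencing depth: a read from a region shared by several references of *one*
sample organism sees the same depth everywhere it maps, whereas a read from
a region shared between *different* organisms usually sees discordant
depths. The criterion is relative,

    (max(D_r) - min(D_r)) / mean(D_r) <= t,

with D_r the depths of the read's target references and t a user threshold
(default 0.2). Higher t admits more reads as CR, useful when depth estimates
are noisy (novel organisms, low coverage). Single-target reads are trivially
CR. Organisms of equal depth can still produce false CR; the clustering
stage is designed to tolerate this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = ["CoreReadContext", "CoreReadSet", "is_core_read", "extract_core_reads"]

DEFAULT_T = 0.2


@dataclass
class CoreReadContext:
    """Inputs to CR extraction.

    ``depth_of`` holds the fitted per-reference depths; reads with any target
    lacking a depth (failed fit) are excluded from CR, since the criterion is
    a depth comparison.
    """

    depth_of: Mapping[str, float]
    targets_of: Mapping[str, Iterable[str]]
    t: float = DEFAULT_T

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("threshold t must be >= 0")


@dataclass
class CoreReadSet:
    core: set[str]
    per_organism_cr: dict[str, set[str]] = field(default_factory=dict)

    def cr_of(self, organism: str) -> set[str]:
        return self.per_organism_cr.get(organism, set())


def is_core_read(depths: list[float], t: float) -> bool:
    """Apply the relative depth-spread criterion to one read's target depths."""
    if not depths:
        raise ValueError("empty depth list")
    lo, hi = min(depths), max(depths)
    if hi == lo:  # singletons and exactly equal depths always qualify
        return True
    mean = sum(depths) / len(depths)
    return (hi - lo) / mean <= t


def extract_core_reads(ctx: CoreReadContext) -> CoreReadSet:
    """All core reads plus the CR set of each organism."""
    core: set[str] = set()
    per_org: dict[str, set[str]] = {}
    for read_id, targets in ctx.targets_of.items():
        targets = list(targets)
        if any(org not in ctx.depth_of for org in targets):
            continue
        depths = [ctx.depth_of[org] for org in targets]
        if is_core_read(depths, ctx.t):
            core.add(read_id)
            for org in targets:
                per_org.setdefault(org, set()).add(read_id)
    return CoreReadSet(core=core, per_organism_cr=per_org)
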