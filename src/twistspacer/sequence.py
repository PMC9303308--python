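"""Sequence-dependent refinement of the orientational energy.

Crystallographic surveys show that the intrinsic twist of a dinucleotide step
varies by roughly a factor of two with its sequence.  Here the spacer is
modelled as torsional springs in series -- one per dinucleotide step, with
intrinsic twist ``alpha_i`` and stiffness ``k_i`` -- while RNA polymerase
imposes the total twist angle ``theta_P`` across the spacer.  Minimizing the
elastic energy under that total-angle constraint gives the closed form

    E = (1/2) * k_eff * (theta_P - (1 + sigma) * sum_i alpha_i)**2,
    k_eff = 1 / sum_i (1 / k_i),

which reduces exactly to the uniform-DNA model when every step carries
``(alpha_0, k_theta)``.  Two ablations isolate where the sequence effect comes
from: replacing every ``alpha_i`` by the panel average removes the structural
heterogeneity, replacing every ``k_i`` removes the elastic heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidSequenceError
from .torsion import DEG, DEFAULT_PARAMS, TwistParameters

__all__ = [
    "DinucleotideTwistTable",
    "SpacerSequence",
    "sequence_mean_twist",
    "effective_stiffness",
    "sequence_orientational_energy",
    "sequence_adjustment_span",
    "SpanResult",
    "read_spacer_fasta",
]

_BASES = "ACGT"
_STEPS = tuple(a + b for a in _BASES for b in _BASES)


@dataclass(frozen=True)
class DinucleotideTwistTable:
    """Per-dinucleotide intrinsic twist (radians) and stiffness (k_B*T/rad^2).

    ``entries`` maps each of the 16 steps over {A,C,G,T} to an
    ``(alpha_i, k_i)`` pair; both must be positive.
    """

    entries: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        keys = set(self.entries)
        if keys != set(_STEPS):
            missing = sorted(set(_STEPS) - keys)
            extra = sorted(keys - set(_STEPS))
            raise ValueError(
                f"table must define exactly the 16 ACGT dinucleotide steps; "
                f"missing={missing} extra={extra}"
            )
        for step, (alpha, k) in self.entries.items():
            if not (alpha > 0 and k > 0):
                raise ValueError(f"step {step}: alpha and k must be > 0")

    @classmethod
    def uniform(cls, params: TwistParameters = DEFAULT_PARAMS) -> "DinucleotideTwistTable":
        """All 16 steps carry the sequence-averaged ``(alpha0, k_theta)``."""
        return cls({s: (params.alpha0, params.k_theta) for s in _STEPS})

    @classmethod
    def from_degrees(cls, twist_deg: Mapping[str, float], stiffness: Mapping[str, float]) -> "DinucleotideTwistTable":
        return cls({s: (twist_deg[s] * DEG, stiffness[s]) for s in _STEPS})

    @classmethod
    def from_tsv(cls, path) -> "DinucleotideTwistTable":
        """Read a TSV with columns ``step``, ``twist_deg``, ``stiffness``."""
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"step", "twist_deg", "stiffness"}
        if not required.issubset(df.columns):
            raise ValueError(f"twist table needs columns {sorted(required)}")
        return cls(
            {
                str(r.step): (float(r.twist_deg) * DEG, float(r.stiffness))
                for r in df.itertuples()
            }
        )

    @classmethod
    def default(cls) -> "DinucleotideTwistTable":
        """The packaged crystallographic-compilation table (see data file header)."""
        ref = resources.files("twistspacer.data").joinpath("dinucleotide_twist.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def alpha(self, step: str) -> float:
        return self.entries[step][0]

    def k(self, step: str) -> float:
        return self.entries[step][1]

    def with_uniform_alpha(self, alpha: float) -> "DinucleotideTwistTable":
        return DinucleotideTwistTable({s: (alpha, k) for s, (_, k) in self.entries.items()})

    def with_uniform_k(self, k: float) -> "DinucleotideTwistTable":
        return DinucleotideTwistTable({s: (a, k) for s, (a, _) in self.entries.items()})


@dataclass(frozen=True)
class SpacerSequence:
    """A spacer sequence with optional flanking bases from the hexamers.

    Steps are counted between consecutive spacer nucleotides (``n - 1`` steps
    for an ``n``-nt spacer).  When flanks are provided and requested, the two
    boundary steps into the hexamers are added (``n + 1`` steps).
    """

    seq: str
    flank5: str = ""
    flank3: str = ""
    promoter_id: str | None = None

    def __post_init__(self) -> None:
        for name, s in (("seq", self.seq), ("flank5", self.flank5), ("flank3", self.flank3)):
            if any(c not in _BASES for c in s):
                raise InvalidSequenceError(
                    f"{name} contains non-ACGT characters: {s!r}"
                )

    def steps(self, include_flanks: bool = False) -> list[str]:
        s = self.seq
        if include_flanks:
            if not (self.flank5 and self.flank3):
                raise InvalidSequenceError(
                    "include_flanks requires both flanking bases"
                )
            s = self.flank5[-1] + s + self.flank3[0]
        if len(s) < 2:
            raise InvalidSequenceError(
                f"need at least 2 nt for a step-wise computation, got {s!r}"
            )
        return [s[i : i + 2] for i in range(len(s) - 1)]


def sequence_mean_twist(
    spacer: SpacerSequence,
    table: DinucleotideTwistTable,
    include_flanks: bool = False,
) -> float:
    """Total intrinsic twist of the spacer, radians (sum of per-step alphas)."""
    return float(sum(table.alpha(s) for s in spacer.steps(include_flanks)))


def effective_stiffness(
    spacer: SpacerSequence,
    table: DinucleotideTwistTable,
    include_flanks: bool = False,
) -> float:
    """Series-spring stiffness ``1 / sum(1/k_i)`` of the spacer, k_B*T/rad^2."""
    return float(1.0 / sum(1.0 / table.k(s) for s in spacer.steps(include_flanks)))


def sequence_orientational_energy(
    spacer: SpacerSequence,
    sigma: float,
    theta_p: float,
    table: DinucleotideTwistTable,
    include_flanks: bool = False,
) -> float:
    """Minimum elastic energy (k_B*T) with RNAP imposing total angle ``theta_p``.

    Closed form of the constrained quadratic minimum over per-step angles;
    reduces to the uniform-DNA orientational energy for a uniform table.
    """
    total_alpha = sequence_mean_twist(spacer, table, include_flanks)
    k_eff = effective_stiffness(spacer, table, include_flanks)
    dev = theta_p - total_alpha * (1.0 + sigma)
    return 0.5 * k_eff * dev * dev


def _uniform_energy_per_steps(
    m_steps: int, sigma: float, theta_p: float, params: TwistParameters
) -> float:
    dev = theta_p - m_steps * params.alpha0 * (1.0 + sigma)
    return 0.5 * (params.k_theta / m_steps) * dev * dev


@dataclass(frozen=True)
class SpanResult:
    """Per-promoter energy adjustments (k_B*T) and their max - min span."""

    adjustments: np.ndarray
    span: float
    mode: str


def sequence_adjustment_span(
    promoters: Iterable[SpacerSequence],
    sigma: float,
    theta_p: float,
    table: DinucleotideTwistTable,
    mode: Literal["full", "average_alpha", "average_k"] = "full",
    params: TwistParameters = DEFAULT_PARAMS,
    include_flanks: bool = False,
) -> SpanResult:
    """Energy adjustment of each promoter relative to the uniform model.

    For every spacer the adjustment is the sequence-dependent energy minus the
    uniform-DNA energy over the same number of steps.  ``average_alpha``
    replaces every step's intrinsic twist by the panel-average twist per step
    (removing structural heterogeneity; only stiffness heterogeneity remains),
    ``average_k`` likewise averages the stiffness (removing elastic
    heterogeneity).  The span (max - min) measures how much regulatory spread
    the sequence alone can generate across the panel.
    """
    promoters = list(promoters)
    if not promoters:
        raise ValueError("promoter list is empty")
    if mode not in ("full", "average_alpha", "average_k"):
        raise ValueError(f"unknown mode {mode!r}")

    all_steps = [step for p in promoters for step in p.steps(include_flanks)]
    work = table
    if mode == "average_alpha":
        mean_alpha = float(np.mean([table.alpha(s) for s in all_steps]))
        work = table.with_uniform_alpha(mean_alpha)
    elif mode == "average_k":
        mean_k = float(np.mean([table.k(s) for s in all_steps]))
        work = table.with_uniform_k(mean_k)

    adjustments = np.array(
        [
            sequence_orientational_energy(p, sigma, theta_p, work, include_flanks)
            - _uniform_energy_per_steps(
                len(p.steps(include_flanks)), sigma, theta_p, params
            )
            for p in promoters
        ]
    )
    return SpanResult(
        adjustments=adjustments,
        span=float(adjustments.max() - adjustments.min()),
        mode=mode,
    )


def read_spacer_fasta(path) -> list[SpacerSequence]:
    """Read spacer sequences from FASTA; record ids become promoter ids."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(SpacerSequence(seq=str(rec.seq).upper(), promoter_id=rec.id))
    return out
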