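"""Run configuration: every user-settable knob with validated defaults."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields

from .profile_space import AlphabetSpec, BaseScoringParams, default_base_table

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the discrete-profile MSA pipeline.

    Codebook: ``lattice_l`` lattice points per axis (L), purine/pyrimidine
    filter thresholds ``t_c``/``t_d``, symbol cap ``max_symbols``.
    Scoring: nucleotide match/transition/transversion scores, linear
    ``gap_extend`` per gap position, ``beta`` scaling (None = smallest
    fitting power of two) and the 4/8-bit ``entry_bits`` budget.
    Reduction: ``reduction_scale`` quantization levels per axis (Q).
    Progressive: ``kmer`` word length for Stage-1 distances and ``maxiters``
    (1 or 2) iterations.
    """

    lattice_l: int = 4
    t_c: float = 0.75
    t_d: float = 0.30
    apply_filter: bool = True
    max_symbols: int = 64
    match: float = 5.0
    transition: float = -2.0
    transversion: float = -4.0
    gap_extend: float = -4.0
    gap_gap: float = 0.0
    beta: float | None = None
    entry_bits: int = 8
    reduction_scale: int = 16
    kmer: int = 6
    maxiters: int = 2
    seqtype: str = "dna"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.maxiters not in (1, 2):
            raise ValueError("maxiters must be 1 or 2")
        if self.seqtype not in ("dna", "rna"):
            raise ValueError("seqtype must be 'dna' or 'rna'")
        if self.kmer < 1:
            raise ValueError("kmer must be >= 1")
        if self.reduction_scale < self.lattice_l:
            raise ValueError("reduction_scale must be >= lattice_l")
        if self.gap_extend > 0:
            raise ValueError("gap_extend must be <= 0")
        if not 0.0 <= self.t_c <= 1.0 or not 0.0 <= self.t_d <= 1.0:
            raise ValueError("t_c and t_d must lie in [0, 1]")

    def scoring_params(self, alphabet: AlphabetSpec) -> BaseScoringParams:
        s = default_base_table(
            alphabet, match=self.match, transition=self.transition,
            transversion=self.transversion, gap_extend=self.gap_extend,
            gap_gap=self.gap_gap,
        )
        return BaseScoringParams(s=s, gap_open=self.gap_extend,
                                 gap_extend=self.gap_extend, beta=self.beta,
                                 entry_bits=self.entry_bits)

    def cache_key(self) -> tuple:
        """Hashable key over the fields that determine the pipeline tables."""
        return (self.lattice_l, self.t_c, self.t_d, self.apply_filter,
                self.max_symbols, self.match, self.transition, self.transversion,
                self.gap_extend, self.gap_gap, self.beta, self.entry_bits,
                self.reduction_scale)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)
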