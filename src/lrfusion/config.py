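"""Tunable thresholds for fusion calling.

All defaults match the documented behaviour of the two-phase caller: a 70%
minimum alignment identity for chimeric segments, exon-boundary proximity
rules of 50 bases (strict) and 1 kb (relaxed, multi-read), a minimum fusion
expression of 0.1 FFPM, 3-base snapping of alignment ends onto exon
boundaries, a 25-base per-gene exonic anchor for fusion-supporting reads, a
two-read minimum at non-consensus splice breakpoints, and a 5% dominant
isoform fraction cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class FusionCallingConfig:
    # phase 1: chimeric read scan
    min_identity: float = 0.70
    max_boundary_dist_strict: int = 50
    max_boundary_dist_relaxed: int = 1000
    min_reads_relaxed: int = 2
    min_ffpm: float = 0.1
    locus_separation: int = 100_000
    paralog_filter: bool = True

    # phase 2: fusion contig modelling and quantification
    intron_cap: int = 1000          # introns longer than this are shrunk ...
    intron_flank: int = 500         # ... to this many bases kept at each end
    spacer_len: int = 1000          # run of N between the two genes on the contig
    snap_dist: int = 3
    min_per_side_exon_bp: int = 25
    min_reads_nonconsensus: int = 2
    isoform_frac: float = 0.05
    consensus_dinucleotides: frozenset[tuple[str, str]] = field(
        default_factory=lambda: frozenset({("GT", "AG")})
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")
        if self.intron_flank * 2 != self.intron_cap:
            # kept flanks define the shrunk intron length
            raise ValueError("intron_cap must equal 2 * intron_flank")


DEFAULT_CONFIG = FusionCallingConfig()
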