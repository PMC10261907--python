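"""Exception hierarchy for fusionscope."""


class FusionScopeError(Exception):
    """Base class for all fusionscope errors."""


class UnknownGeneError(FusionScopeError):
    """A requested gene id has no records in the annotation."""


class AmbiguousLocusError(FusionScopeError):
    """A gene has exons on multiple chromosomes or strands."""


class SelfFusionError(FusionScopeError):
    """geneA and geneB are the same gene."""


class CrossContigPairError(FusionScopeError):
    """Mates of one fragment align to different fusion contigs."""


class EdgeBreakpointError(FusionScopeError):
    """Breakpoint too close to a contig edge to read flanking bases."""
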