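"""Exception hierarchy shared by all tfdyn modules."""


class TFDynError(Exception):
    """Base class for all tfdyn errors."""


class EmptyStructureError(TFDynError):
    """A structure with zero retained nodes where at least one is required."""


class TopologyError(TFDynError):
    """Two structures that must share a topology (node count / identity) do not."""


class DomainLookupError(TFDynError, KeyError):
    """A domain name does not exist in a DomainMap, or resolves to no nodes."""


class DegenerateAlignmentError(TFDynError):
    """Superposition attempted with <3 paired nodes or a collinear node set."""


class DisconnectedNetworkError(TFDynError):
    """Elastic network is not a single connected component.

    Carries the component sizes so the caller can diagnose a bad cutoff.
    """

    def __init__(self, component_sizes):
        self.component_sizes = tuple(sorted(component_sizes, reverse=True))
        super().__init__(
            f"elastic network has {len(self.component_sizes)} connected "
            f"components of sizes {self.component_sizes}; increase the cutoff"
        )


class ZeroModeCountError(TFDynError):
    """A connected 3-D network did not yield exactly six near-zero modes."""


class UndefinedOverlapError(TFDynError):
    """Overlap requested between vectors at least one of which has zero norm."""


class GenerationError(TFDynError):
    """Synthetic-structure generation failed (packing did not converge)."""


class RelaxationError(TFDynError):
    """A relaxation backend returned a structure violating its contract."""
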