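"""Exception hierarchy for ssrforge.

All user-facing errors derive from :class:`SSRForgeError` so the CLI can map
them to exit code 1; anything else is an internal error (exit code 2).
"""


class SSRForgeError(Exception):
    """Base class for all ssrforge user errors."""


class InvalidAlphabetError(SSRForgeError):
    """Sequence or motif contains characters outside the allowed alphabet."""


class InvalidMotifError(SSRForgeError):
    """Motif is not primitive (it is a power of a shorter unit)."""


class MissingSequenceError(SSRForgeError):
    """A referenced sequence id is absent from the sequence store."""


class HitTableParseError(SSRForgeError):
    """Malformed alignment hit table row; message names the line number."""


class NoHitError(SSRForgeError):
    """Single-copy test called with an empty score list."""


class FragmentTooShortError(SSRForgeError):
    """Query fragment is shorter than the seed k-mer length."""


class NoDataError(SSRForgeError):
    """A marker has no non-missing genotype calls."""


class FrequencySumError(SSRForgeError):
    """Allele frequencies do not sum to 1 within tolerance."""


class UnknownGroupError(SSRForgeError):
    """Requested accession group does not exist in the genotype matrix."""


class NoSharedLociError(SSRForgeError):
    """A pair of accessions shares no loci with non-missing calls."""


class InvalidDistanceMatrixError(SSRForgeError):
    """Distance matrix is asymmetric, has negative entries or nonzero diagonal."""


class InfeasiblePlacementError(SSRForgeError):
    """Planted SSR specs cannot be placed in the requested genome."""


class ConfigError(SSRForgeError):
    """Run configuration is invalid (unknown key, missing path, bad value)."""
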