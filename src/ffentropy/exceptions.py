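"""Exception hierarchy for ffentropy.

Every error raised deliberately by the library derives from
:class:`FFEntropyError`, so callers (and the CLI) can distinguish
domain errors from programming errors.
"""


class FFEntropyError(Exception):
    """Base class for all ffentropy errors."""


class ParseError(FFEntropyError):
    """A structure or trajectory file could not be parsed."""


class TopologyMismatchError(FFEntropyError):
    """Trajectory atom count disagrees with the topology atom count."""

    def __init__(self, trajectory_atoms: int, topology_atoms: int):
        self.trajectory_atoms = trajectory_atoms
        self.topology_atoms = topology_atoms
        super().__init__(
            f"trajectory has {trajectory_atoms} atoms but topology has "
            f"{topology_atoms} atoms"
        )


class SelectionError(FFEntropyError):
    """An atom or residue selection is empty or invalid."""


class ParameterError(FFEntropyError):
    """A numeric parameter is outside its documented range."""


class InsufficientDataError(FFEntropyError):
    """Not enough frames/blocks/values to compute the requested statistic."""


class DegenerateGeometryError(FFEntropyError):
    """Point configuration too degenerate for a unique superposition."""
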