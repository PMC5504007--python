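"""Exception hierarchy for gridstitch.

Exit-code mapping used by the CLI:
  2 — argument/usage errors (PatternError and click's own usage errors)
  3 — data errors (unreadable tiles, malformed positions files, shape mismatches)
  4 — stage-model failure ("cannot model stage")
"""


class StitchError(Exception):
    """Base class for all gridstitch errors."""


class PatternError(StitchError):
    """Filename pattern is malformed or cannot address the requested grid."""


class DataError(StitchError):
    """Input data is missing, unreadable or inconsistent with the grid."""


class GridShapeError(DataError):
    """A tile grid violates the rectangular, uniform-tile-size contract."""


class StageModelError(StitchError):
    """No direction yields a trusted estimate and no user parameters were given."""
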