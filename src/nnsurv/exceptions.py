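"""Exception hierarchy.

Two failure modes are distinguished throughout the package:

* :class:`ValidationError` -- the *data* violate an invariant (non-positive
  duration, event indicator outside {0, 1}, shape mismatch, ...).
* :class:`ConfigurationError` -- the *caller's setup* is wrong (missing column,
  invalid grid size, unknown interpolation scheme, empty validation split, ...).

Both derive from :class:`ValueError` so generic handling still works.
"""


class ValidationError(ValueError):
    """Input data violate a documented invariant."""


class ConfigurationError(ValueError):
    """The requested configuration is invalid or inconsistent."""
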