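"""Exception hierarchy.

``PpiScreenError`` is the common base so callers can catch everything the
package raises deliberately.  ``ParseError``/``ValidationError`` mark bad
input data; anything else escaping the package is a genuine bug.
"""


class PpiScreenError(Exception):
    """Base class for all errors raised by ppiscreen."""


class ParseError(PpiScreenError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PpiScreenError):
    """Parsed input violates a domain contract (bad mode, bad config ...)."""
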