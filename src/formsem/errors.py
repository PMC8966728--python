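"""Exception hierarchy for formsem."""


class FormsemError(Exception):
    """Base class for all formsem errors."""


class LexiconFormatError(FormsemError):
    """The annotation table violates the input contract (e.g. no gloss column)."""


class EmbeddingFormatError(FormsemError):
    """The embedding file is empty or its dimension does not match."""


class EmptyFeatureSpaceError(FormsemError):
    """A parameter scope has no observed annotation labels at all."""


class NoOverlapError(FormsemError):
    """No lexicon gloss has an embedding vector."""


class ParameterError(FormsemError, ValueError):
    """An argument is outside its documented range."""
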