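"""Exception hierarchy for tcrconv."""


class TCRConvError(Exception):
    """Base class for all tcrconv errors."""


class FormatError(TCRConvError):
    """An input table does not conform to the declared dialect."""


class FrameError(TCRConvError):
    """A nucleotide sequence is not a whole number of codons."""


class DataError(TCRConvError):
    """Input data are internally inconsistent (e.g. one rearrangement
    reported with two different amino-acid translations)."""


class ConfigurationError(TCRConvError):
    """An operation was invoked on input in the wrong state
    (e.g. convergence grouping on an unfiltered repertoire)."""


class ParameterError(TCRConvError):
    """A parameter value is outside its admissible range."""


class UndefinedStatisticError(TCRConvError):
    """The requested statistic is mathematically undefined for this input
    (signalled explicitly rather than returning a silent default)."""
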