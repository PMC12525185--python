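"""Exception hierarchy shared by all modules."""


class SmilesCwError(Exception):
    """Base class for all package errors."""


class MalformedSmilesError(SmilesCwError):
    """A SMILES string cannot be normalized or tokenized."""


class DegenerateDescriptorError(SmilesCwError):
    """The descriptor has zero variance, so no calibration line exists."""


class UndefinedStatisticError(SmilesCwError):
    """A statistic is undefined for the given data (e.g. constant vectors)."""


class UnknownAttributeError(SmilesCwError):
    """An attribute is absent from every modeling set, so its defect has no data."""


class DatasetError(SmilesCwError):
    """A dataset or split violates a structural requirement."""


class ModelIOError(SmilesCwError):
    """A model artifact cannot be read or is from an incompatible version."""
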