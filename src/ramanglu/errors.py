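"""Exception hierarchy shared across the package."""


class RamanGluError(Exception):
    """Base class for all package-specific errors."""


class MalformedSpectrum(RamanGluError):
    """A spectrum file or array violates a structural invariant
    (non-numeric row, negative intensity, non-ascending shift axis)."""


class MissingLabel(RamanGluError):
    """A spectrum filename carries no parseable integer label prefix."""


class AxisMismatch(RamanGluError):
    """Spectra in one dataset (or a mask and a dataset) disagree on the
    shift axis."""


class EmptyDataset(RamanGluError):
    """An operation that needs at least one spectrum received none."""


class InvalidWindow(RamanGluError):
    """A window length is out of range or has the wrong parity."""


class InvalidParams(RamanGluError):
    """Generator or algorithm parameters violate their invariants."""


class SingularFit(RamanGluError):
    """The shift axis has too few distinct values to fit the requested
    polynomial order."""


class InvalidGrid(RamanGluError):
    """A grid-search space names a hyperparameter the model does not
    accept."""


class StratificationError(RamanGluError):
    """Stratified cross-validation is impossible: some class has fewer
    samples than folds."""


class DegenerateClassWarning(UserWarning):
    """A class is absent from the true labels, so its one-vs-rest
    sensitivity is undefined and it is excluded from macro averages."""
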