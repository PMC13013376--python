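"""Exception hierarchy for netshift."""


class NetshiftError(Exception):
    """Base class for all netshift errors."""


class ConfigurationError(NetshiftError):
    """Invalid configuration: bad band limits, empty pass-band, non-PD target, ..."""


class DegenerateDataError(NetshiftError):
    """Input data admit no answer: constant differences, all-zero diffs, ..."""


class DegenerateThresholdError(NetshiftError):
    """Proportional threshold retains no edge, or every edge."""


class UndefinedMetricError(NetshiftError):
    """A graph metric is undefined on this input (edgeless graph, no eligible nodes, ...)."""


class ZeroVarianceError(NetshiftError):
    """A region's time series has zero variance; correlation is undefined."""

    def __init__(self, regions):
        self.regions = list(regions)
        super().__init__(f"zero-variance time series in region(s): {self.regions}")
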