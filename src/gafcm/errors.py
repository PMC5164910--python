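"""Exception types shared across the package."""


class DegenerateClusterError(RuntimeError):
    """A cluster received zero total membership mass, so its center is undefined.

    Parameters
    ----------
    clusters : sequence of int
        Indices of the degenerate clusters.
    """

    def __init__(self, clusters):
        self.clusters = tuple(int(c) for c in clusters)
        super().__init__(
            f"cluster(s) {self.clusters} have zero membership mass; "
            "center update is undefined"
        )


class DegeneratePixelError(RuntimeError):
    """A pixel's combined membership/spatial weights are all zero."""


class SelectionFailureError(RuntimeError):
    """No chromosome with finite cost is available for parent selection."""
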