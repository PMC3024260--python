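"""compdbn: ODE + dynamic-Bayesian-network modelling of complement activation.

A kinetic model of classical/lectin complement activation with CRP:L-ficolin
crosstalk amplification and C4BP inhibition, approximated as a discretized
dynamic Bayesian network for factored-frontier inference, two-stage parameter
estimation and multi-parametric sensitivity analysis.
"""

from importlib import resources

__version__ = "0.1.0"


def complement_model_path():
    """Path to the bundled canonical complement model file."""
    return resources.files("compdbn").joinpath("data/complement.yaml")


def load_complement():
    """Load the bundled 42-species complement reaction network."""
    from .io import read_model

    return read_model(complement_model_path())


def affinity_anchor_path():
    return resources.files("compdbn").joinpath("data/affinity_anchors.csv")
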