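"""Registry mapping method ids to adjusted-value producers.

Every entry takes a :class:`~mtlab.core.PValueVector` and returns
:class:`~mtlab.core.AdjustedPValues`; thresholding the result at ``alpha``
yields that procedure's decisions.  ``STUDY_METHODS`` is the eight-method
panel compared in the simulation study; ``holm`` and ``hochberg`` are
registered as well for standalone use.
"""

from __future__ import annotations

from typing import Callable

from .core import AdjustedPValues, PValueVector
from .fdr_control import bh_adjust, by_adjust, tsbh_adjust
from .fdr_estimation import (
    storey_qvalues_adjusted,
    strimmer_lfdr_adjusted,
    strimmer_qvalues_adjusted,
)
from .fwer import bonferroni_adjust, hochberg_adjust, holm_adjust, hommel_adjust

Adjuster = Callable[[PValueVector], AdjustedPValues]

METHOD_REGISTRY: dict[str, Adjuster] = {
    "bonferroni": bonferroni_adjust,
    "holm": holm_adjust,
    "hochberg": hochberg_adjust,
    "hommel": hommel_adjust,
    "bh": bh_adjust,
    "tsbh": tsbh_adjust,
    "by": by_adjust,
    "qvalue-storey": storey_qvalues_adjusted,
    "qvalue-strimmer": strimmer_qvalues_adjusted,
    "lfdr": strimmer_lfdr_adjusted,
}

def adjusted_values(name: str, pv: PValueVector, alpha: float = 0.05) -> AdjustedPValues:
    """Dispatch by method id.

    The two-stage procedure is the one registry entry whose decisions depend
    on ``alpha`` beyond the final threshold, so it is dispatched with the
    level while every other method ignores it.
    """
    if name not in METHOD_REGISTRY:
        raise KeyError(
            f"unknown method {name!r}; valid ids: {', '.join(sorted(METHOD_REGISTRY))}"
        )
    if name == "tsbh":
        return tsbh_adjust(pv, alpha=alpha)
    return METHOD_REGISTRY[name](pv)


# the eight procedures compared head-to-head in the power/specificity study
STUDY_METHODS: tuple[str, ...] = (
    "bonferroni",
    "hommel",
    "bh",
    "tsbh",
    "by",
    "qvalue-storey",
    "qvalue-strimmer",
    "lfdr",
)
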