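"""EquiFACS code vocabulary.

The Equine Facial Action Coding System names anatomically based facial
movements in four namespaces: action units (``AU``, muscle-based movements
such as AU101 *inner brow raiser*), action descriptors (``AD``, e.g. AD38
*nostril dilator*), ear action descriptors (``EAD``), and supplemental horse
codes (``AUH``). ``VC74`` is the visibility code marking unscorable footage.
``FMI_EAR_FLICKER`` is not an EquiFACS code but the composite "ear flicker"
facial movement index produced by :mod:`facs_affect.fmi`.

Head-movement descriptors (AD51--AD55) are deliberately absent: annotation
templates in this kind of study exclude them.
"""

from __future__ import annotations

EAR_FORWARD = "EAD101"
EAR_ROTATOR = "EAD104"
UNSCORABLE = "VC74"
FLICKER = "FMI_EAR_FLICKER"

#: Lower-face and eye-region action units.
ACTION_UNITS = frozenset({
    "AU101",  # inner brow raiser
    "AU143",  # eye closure
    "AU145",  # blink
    "AU47",   # half blink
    "AU5",    # upper lid raiser
    "AU10",   # upper lip raiser
    "AU113",  # sharp lip puller
    "AU12",   # lip corner puller
    "AU16",   # lower lip depressor
    "AU17",   # chin raiser
    "AU122",  # upper lip curler
    "AU24",   # lip presser
    "AU25",   # lips part
    "AU26",   # jaw drop
    "AU27",   # mouth stretch
})

#: Supplemental horse-specific action units.
SUPPLEMENTAL_UNITS = frozenset({
    "AUH13",  # nostril lift
    "AUH21",  # platysma tightener
})

#: Action descriptors (effects of several muscles, not a single AU).
ACTION_DESCRIPTORS = frozenset({
    "AD1",    # eye white increase
    "AD19",   # tongue show
    "AD29",   # jaw thrust
    "AD30",   # jaw sideways
    "AD38",   # nostril dilator
    "AD76",   # vocalization accompaniment
    "AD81",   # chewing
    "AD133",  # blow
    "AD160",  # lower lip relax
})

#: Ear action descriptors.
EAR_DESCRIPTORS = frozenset({
    "EAD101",  # ears forward
    "EAD102",  # ear adductor
    "EAD103",  # ear flattener
    "EAD104",  # ear rotator
})

#: Every code accepted by default, including the visibility code and the
#: composite ear-flicker index.
DEFAULT_VOCABULARY = frozenset(
    ACTION_UNITS
    | SUPPLEMENTAL_UNITS
    | ACTION_DESCRIPTORS
    | EAR_DESCRIPTORS
    | {UNSCORABLE, FLICKER}
)
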