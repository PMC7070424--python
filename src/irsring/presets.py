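"""Object templates for the laboratory drop protocols.

Stone grains are opaque rigid spheres.  The three living microarthropod
taxa used in the laboratory tests differ in cuticle opacity, elongation and
how much they deform (bend appendages) while falling; the template numbers
are plausible morphology-driven settings chosen once, intended to reproduce
the qualitative ordering of detectability between taxa (dark compact mites
easiest, pale deformable springtails hardest), not any species' physical
measurement.
"""

from __future__ import annotations

from dataclasses import replace

from .geometry import ObjectDescriptor

__all__ = [
    "GRAIN",
    "F_CANDIDA",
    "H_NITIDUS",
    "H_ACULEIFER",
    "SPECIES_TEMPLATES",
    "with_size",
]

#: Opaque stone grain (reference particle of the detectability protocol).
GRAIN = ObjectDescriptor(size=1.0, shape="sphere", opacity=1.0, group_label="grain")

#: Pale, elongated springtail; strongly deforms while falling.
F_CANDIDA = ObjectDescriptor(size=1.0, shape="ellipsoid", aspect_ratio=2.8,
                             opacity=0.55, flutter_amplitude=0.5,
                             flutter_frequency=40.0, group_label="F. candida")

#: Shimmering springtail, slightly darker and less deformable.
H_NITIDUS = ObjectDescriptor(size=1.0, shape="ellipsoid", aspect_ratio=2.5,
                             opacity=0.70, flutter_amplitude=0.4,
                             flutter_frequency=40.0, group_label="H. nitidus")

#: Dark, compact predatory mite; nearly rigid in the fall.
H_ACULEIFER = ObjectDescriptor(size=1.0, shape="ellipsoid", aspect_ratio=1.6,
                               opacity=0.95, flutter_amplitude=0.15,
                               flutter_frequency=20.0, group_label="H. aculeifer")

SPECIES_TEMPLATES = {t.group_label: t for t in (GRAIN, F_CANDIDA, H_NITIDUS, H_ACULEIFER)}


def with_size(template: ObjectDescriptor, size: float) -> ObjectDescriptor:
    """A copy of ``template`` with the body size replaced."""
    return replace(template, size=size)
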