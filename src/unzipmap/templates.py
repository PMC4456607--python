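"""Template geometry for unzipping experiments.

A template is a linear DNA of 600-1200 bp carrying a single 601 nucleosome
positioning element (601NPE) and, optionally, a single TF recognition site
(Gal4- or LacO-like).  Physical coordinates run 0..L-1 from the end at which
unzipping starts when ``direction == "from_tf_side"``; by construction the TF
site sits between that end and the nucleosome.  Display ("dyad") coordinates
put the origin at the 601NPE dyad of the *designed* template, matching the
convention used for all position histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

NUC_HALF_FOOTPRINT = 73  # bp of DNA protected on each side of the dyad

FROM_TF_SIDE = "from_tf_side"
FROM_NUC_SIDE = "from_nucleosome_side"
DIRECTIONS = (FROM_TF_SIDE, FROM_NUC_SIDE)


@dataclass(frozen=True)
class TemplateLayout:
    """Geometry of one unzipping template.

    Parameters
    ----------
    template_len : int
        Template length in bp (600-1200 for the layouts used here).
    dyad0 : int
        Dyad of the 601NPE in physical coordinates.
    tf_center : int or None
        Center of the TF recognition site, or None for a TF-free template.
    tf_footprint : int
        Half-width in bp of the TF-protected region (site center +/- footprint).
    separation : int
        Designed gap in bp between the TF site edge and the 601NPE edge.
    direction : str
        Which template end the unzipping fork enters from.
    template_seed : int
        Seed of the naked-DNA force surrogate for this template; traces and
        reference share it so alignment has a common feature landscape.
    """

    template_len: int
    dyad0: int
    tf_center: Optional[int] = None
    tf_footprint: int = 10
    separation: int = 0
    direction: str = FROM_TF_SIDE
    template_seed: int = 20150605

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not 0 < self.dyad0 < self.template_len:
            raise ValueError("dyad must lie inside the template")
        if (self.dyad0 - NUC_HALF_FOOTPRINT < 0
                or self.dyad0 + NUC_HALF_FOOTPRINT > self.template_len - 1):
            raise ValueError("nucleosome footprint (dyad +/- 73 bp) exceeds template")
        if self.tf_center is not None:
            if not 0 < self.tf_center < self.template_len:
                raise ValueError("TF center must lie inside the template")
            if (self.tf_center - self.tf_footprint < 0
                    or self.tf_center + self.tf_footprint > self.template_len - 1):
                raise ValueError("TF footprint exceeds template bounds")

    # --- coordinate transforms -------------------------------------------
    def phys_to_unzip(self, x):
        """Physical bp index -> bp-unzipped coordinate for this direction."""
        if self.direction == FROM_TF_SIDE:
            return x
        return (self.template_len - 1) - x

    def unzip_to_phys(self, u):
        # the map is an involution
        return self.phys_to_unzip(u)

    def phys_to_dyad_frame(self, x):
        """Physical coordinate -> display coordinate with origin at the dyad."""
        return x - self.dyad0

    def unzip_to_dyad_frame(self, u):
        return self.phys_to_dyad_frame(self.unzip_to_phys(u))

    # --- derived geometry -------------------------------------------------
    @property
    def dyad0_unzip(self) -> int:
        return int(self.phys_to_unzip(self.dyad0))

    @property
    def tf_center_unzip(self) -> Optional[int]:
        if self.tf_center is None:
            return None
        return int(self.phys_to_unzip(self.tf_center))

    @property
    def tf_edges(self):
        """Physical extent [lo, hi] of the TF-protected region."""
        if self.tf_center is None:
            return None
        return (self.tf_center - self.tf_footprint, self.tf_center + self.tf_footprint)

    def nuc_edges(self, dyad: Optional[float] = None):
        d = self.dyad0 if dyad is None else dyad
        return (d - NUC_HALF_FOOTPRINT, d + NUC_HALF_FOOTPRINT)

    def with_dyad(self, dyad: float) -> "TemplateLayout":
        """Layout for the same template after the nucleosome moved to ``dyad``."""
        return replace(self, dyad0=int(round(dyad)))

    def with_direction(self, direction: str) -> "TemplateLayout":
        return replace(self, direction=direction)


def build_template(length_bp: int,
                   separation_bp: int,
                   direction: str = FROM_TF_SIDE,
                   end_positioned: bool = False,
                   tf_footprint: int = 10,
                   with_tf: bool = True,
                   template_seed: int = 20150605) -> TemplateLayout:
    """Construct a consistent template layout.

    ``end_positioned`` places the dyad 73 bp from the template end opposite
    the TF side, so the nucleosome footprint touches that end and remodeling
    can only proceed toward the TF.  Otherwise the 601NPE sits at the template
    center.  The TF site is placed so its near edge is ``separation_bp`` from
    the nucleosome edge (dyad - 73).
    """
    if not 600 <= length_bp <= 1200:
        raise ValueError("template length must be in [600, 1200] bp")
    if separation_bp <= 0:
        raise ValueError("separation must be a positive integer")

    dyad0 = length_bp - 1 - NUC_HALF_FOOTPRINT if end_positioned else length_bp // 2
    tf_center = None
    if with_tf:
        tf_center = dyad0 - NUC_HALF_FOOTPRINT - separation_bp - tf_footprint
        if tf_center - tf_footprint < 0:
            raise ValueError("TF footprint falls off the template; "
                             "reduce the separation or use a longer template")
    return TemplateLayout(template_len=length_bp, dyad0=dyad0, tf_center=tf_center,
                          tf_footprint=tf_footprint, separation=separation_bp,
                          direction=direction, template_seed=template_seed)
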