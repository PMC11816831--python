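"""Default sensor geometry.

The craniotomy field is modelled as a plane with the midline at x = 0 and y
increasing towards the front. Defaults follow the experimental counts — two
parasagittal 5-contact subdural strips, 12 IOS ROIs placed symmetrically
(6 per hemisphere) and 4 LSCI ROIs on the right hemisphere — with metric
coordinates chosen by this package (the physical setup reports counts and
strip spacing, not coordinates).
"""

from __future__ import annotations

from .model import CorticalLayout

__all__ = ["default_layout"]


def default_layout(
    contact_spacing_mm: float = 10.0,
    n_contacts_per_strip: int = 5,
    n_ios_rois_per_hemisphere: int = 6,
    ios_roi_spacing_mm: float = 5.0,
) -> CorticalLayout:
    """Build the default two-hemisphere sensor layout.

    ECoG strips run parasagittally at x = +-10 mm starting at y = 0; IOS ROIs
    run at x = +-5 mm starting at y = 2.5 mm; the four LSCI ROIs sit on the
    right hemisphere, numbered front (roi1) to back (roi4) so that a wave
    from a posterior midline origin passes roi4 -> roi1 (parietal to frontal).
    """
    contacts = {}
    for hemi, x in (("left", -10.0), ("right", 10.0)):
        prefix = "L" if hemi == "left" else "R"
        for i in range(n_contacts_per_strip):
            contacts[f"{prefix}{i + 1}"] = (hemi, (x, i * contact_spacing_mm))

    rois_ios = {}
    for hemi, x in (("left", -5.0), ("right", 5.0)):
        prefix = "iosL" if hemi == "left" else "iosR"
        for i in range(n_ios_rois_per_hemisphere):
            rois_ios[f"{prefix}{i + 1}"] = (hemi, (x, 2.5 + i * ios_roi_spacing_mm))

    # LSCI: roi1 most frontal (y = 20), roi4 most parietal (y = 5).
    rois_lsci = {
        f"roi{i}": ("right", (5.0, 25.0 - 5.0 * i)) for i in (1, 2, 3, 4)
    }

    return CorticalLayout(
        contacts=contacts,
        rois_ios=rois_ios,
        rois_lsci=rois_lsci,
        occlusion_site=(0.0, 0.0),
        contact_spacing_mm=contact_spacing_mm,
    )
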