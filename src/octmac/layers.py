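"""Shared naming of the 11 intraretinal surfaces, 10 tissue bands and 8 layers.

Surfaces S1..S11 run anterior to posterior. The half-open band between
consecutive surfaces [S_i, S_{i+1}) is the finest unit the segmentation
produces; the 8 reported layers group them:

    RNFL = [S1, S2)      GCL = [S2, S3)     IPL = [S3, S4)    INL = [S4, S5)
    OPL  = [S5, S6)      ONL = [S6, S7)     PR  = [S7, S10)   RPE = [S10, S11)

The photoreceptor layer spans three bands (inner segment, ellipsoid band and
outer segment; S7 = external limiting membrane, S8 = IS/OS junction,
S9 = OS/RPE interface, S10 = inner RPE boundary), so inner and outer segments
are pooled into one reported layer. The OPL here is the inner (synaptic) third
of the anatomical OPL; Henle fibers are counted with ONL.
"""

N_SURFACES = 11

SURFACE_NAMES = [
    "ILM", "RNFL/GCL", "GCL/IPL", "IPL/INL", "INL/OPL", "OPL/ONL",
    "ELM", "IS/OS", "OS/RPE", "innerRPE", "outerRPE",
]

# the 10 bands between consecutive surfaces, anterior to posterior
BAND_NAMES = ["RNFL", "GCL", "IPL", "INL", "OPL", "ONL", "IS", "EZ", "OS", "RPE"]

LAYER_NAMES = ["RNFL", "GCL", "IPL", "INL", "OPL", "ONL", "PR", "RPE"]

# layer -> (first surface index, last surface index) as 0-based half-open span
LAYER_SPAN = {
    "RNFL": (0, 1),
    "GCL": (1, 2),
    "IPL": (2, 3),
    "INL": (3, 4),
    "OPL": (4, 5),
    "ONL": (5, 6),
    "PR": (6, 9),
    "RPE": (9, 10),
}

# band index -> reported layer
BAND_TO_LAYER = ["RNFL", "GCL", "IPL", "INL", "OPL", "ONL", "PR", "PR", "PR", "RPE"]

# nominal band thickness as a fraction of the depth axis; shared by the
# phantom geometry and the segmenter's anatomical position priors
BAND_THICKNESS_FRAC = (
    12 / 256, 11 / 256, 10 / 256, 9 / 256, 7 / 256,
    20 / 256, 6 / 256, 5 / 256, 5 / 256, 8 / 256,
)
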