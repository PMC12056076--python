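"""Default ROI vocabulary: the 25 combined white-matter skeleton measures.

Bilateral JHU-atlas regions are assumed to be already averaged across
hemispheres upstream; AverageFA is the mean over the full skeleton.
"""

DEFAULT_ROIS = [
    "AverageFA",
    "ACR",   # anterior corona radiata
    "ALIC",  # anterior limb of internal capsule
    "BCC",   # body of corpus callosum
    "CC",    # corpus callosum
    "CGC",   # cingulum (cingulate gyrus)
    "CGH",   # cingulum (hippocampus)
    "CR",    # corona radiata
    "CST",   # corticospinal tract
    "EC",    # external capsule
    "FX",    # fornix
    "FXST",  # fornix (crus) / stria terminalis
    "GCC",   # genu of corpus callosum
    "IC",    # internal capsule
    "PCR",   # posterior corona radiata
    "PLIC",  # posterior limb of internal capsule
    "PTR",   # posterior thalamic radiation
    "RLIC",  # retrolenticular part of internal capsule
    "SCC",   # splenium of corpus callosum
    "SCR",   # superior corona radiata
    "SFO",   # superior fronto-occipital fasciculus
    "SLF",   # superior longitudinal fasciculus
    "SS",    # sagittal stratum
    "TAP",   # tapetum
    "UNC",   # uncinate fasciculus
]
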