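# Composite-region definitions used throughout the package.
#
# Each composite is built from one of three sources:
#   measure: a whole-brain summary measure from the aseg.stats header
#   aseg:    a list of aseg.stats segmentation structure names (summed)
#   dkt:     a list of DKT cortical parcel names (summed over both hemispheres)
#
# The cortical groupings follow the standard lobar assignment of the 31 DKT
# parcels; the ventricle composite is the full ventricular system. Both are
# conventions, editable here without touching code.
order:
  - brain
  - frontal
  - temporal
  - parietal
  - occipital
  - cingulate
  - insular
  - ventricle
  - thalamus
  - putamen
  - hippocampus
  - caudate
  - amygdala
  - pallidus
  - accumbens

regions:
  brain:
    measure: BrainSegVolNotVent
  frontal:
    dkt:
      - superiorfrontal
      - rostralmiddlefrontal
      - caudalmiddlefrontal
      - parsopercularis
      - parstriangularis
      - parsorbitalis
      - lateralorbitofrontal
      - medialorbitofrontal
      - precentral
      - paracentral
  temporal:
    dkt:
      - superiortemporal
      - middletemporal
      - inferiortemporal
      - transversetemporal
      - fusiform
      - entorhinal
      - parahippocampal
  parietal:
    dkt:
      - superiorparietal
      - inferiorparietal
      - supramarginal
      - postcentral
      - precuneus
  occipital:
    dkt:
      - lateraloccipital
      - lingual
      - cuneus
      - pericalcarine
  cingulate:
    dkt:
      - rostralanteriorcingulate
      - caudalanteriorcingulate
      - posteriorcingulate
      - isthmuscingulate
  insular:
    dkt:
      - insula
  ventricle:
    aseg:
      - Left-Lateral-Ventricle
      - Right-Lateral-Ventricle
      - Left-Inf-Lat-Vent
      - Right-Inf-Lat-Vent
      - 3rd-Ventricle
      - 4th-Ventricle
  thalamus:
    aseg:
      - Left-Thalamus-Proper
      - Right-Thalamus-Proper
  putamen:
    aseg:
      - Left-Putamen
      - Right-Putamen
  hippocampus:
    aseg:
      - Left-Hippocampus
      - Right-Hippocampus
  caudate:
    aseg:
      - Left-Caudate
      - Right-Caudate
  amygdala:
    aseg:
      - Left-Amygdala
      - Right-Amygdala
  pallidus:
    aseg:
      - Left-Pallidum
      - Right-Pallidum
  accumbens:
    aseg:
      - Left-Accumbens-area
      - Right-Accumbens-area
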