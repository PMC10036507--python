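{
  "version": "1.0",
  "labels": ["frontal", "parietal", "temporal", "occipital", "insular", "subcortex"],
  "cortical": {
    "superiorfrontal": "frontal",
    "rostralmiddlefrontal": "frontal",
    "caudalmiddlefrontal": "frontal",
    "parsopercularis": "frontal",
    "parstriangularis": "frontal",
    "parsorbitalis": "frontal",
    "lateralorbitofrontal": "frontal",
    "medialorbitofrontal": "frontal",
    "precentral": "frontal",
    "paracentral": "frontal",
    "frontalpole": "frontal",
    "rostralanteriorcingulate": "frontal",
    "caudalanteriorcingulate": "frontal",
    "superiorparietal": "parietal",
    "inferiorparietal": "parietal",
    "supramarginal": "parietal",
    "postcentral": "parietal",
    "precuneus": "parietal",
    "posteriorcingulate": "parietal",
    "isthmuscingulate": "parietal",
    "superiortemporal": "temporal",
    "middletemporal": "temporal",
    "inferiortemporal": "temporal",
    "bankssts": "temporal",
    "fusiform": "temporal",
    "transversetemporal": "temporal",
    "entorhinal": "temporal",
    "temporalpole": "temporal",
    "parahippocampal": "temporal",
    "lateraloccipital": "occipital",
    "lingual": "occipital",
    "cuneus": "occipital",
    "pericalcarine": "occipital",
    "insula": "insular"
  },
  "subcortical": {
    "thalamus": "subcortex",
    "caudate": "subcortex",
    "putamen": "subcortex",
    "pallidum": "subcortex",
    "hippocampus": "subcortex",
    "amygdala": "subcortex",
    "accumbens": "subcortex"
  }
}
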