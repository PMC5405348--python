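{
  "description": "Observed motif-region spans reported in predicted nitrilases, keyed by motif id; columns index the nine anonymous source proteins. Used as positive controls for the fuzzy matcher.",
  "snippets": {
    "ali-1": {"1": "AFPEVFVPAYPY", "2": "FPELWLPGYPIF", "3": "FPEVFISGYPYWNW", "7": "FPEVFIAGY", "8": "FPETFVPYYPY"},
    "ali-2": {"1": "LRRKLVPTW", "2": "RRKLKPTHVER", "3": "RKLVPTWAEKLT", "7": "RHRKLVPTWAER", "8": "RRKITPTYHER"},
    "ali-3": {"1": "CGENTNTLA", "2": "CAENMQPL", "3": "CGENTNTLA", "7": "CGENTNTLARFS", "8": "CWEHYNPL"},
    "ali-4": {"1": "VAAVQAAPVFLDP", "2": "VASVQAE", "3": "VQTAPVFLNVE", "7": "AAVQAAPVFL", "8": "AAVQISPVL"},
    "aro-1": {"4": "FQEVFNA", "5": "PESFIPCYPRG", "6": "FPEAFLGTYP", "9": "SETFSTG"},
    "aro-2": {"4": "RKHHIPQV", "5": "HRKLKPTGLER", "6": "HRKVMPTGAER", "9": "RKLHPFT"},
    "aro-3": {"4": "CYDRH", "5": "CWENYMPLARM", "6": "CWENYMPLLRA", "9": "CYDLRFA"},
    "aro-4": {"4": "AHLWKLE", "5": "ALEGRCFVLA", "6": "ALEGRCWV", "9": "AIENQAYV"}
  }
}
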