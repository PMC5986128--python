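# Experimental-evidence phrases supporting an oligomeric-state statement,
# one per line, matched case-insensitively as substrings of the normalized
# sentence.  Covers the solution methods used to establish stoichiometry:
# chromatography, ultracentrifugation, scattering, native electrophoresis,
# and chemical cross-linking.  Edit or replace via --evidence-kw.
size exclusion chromatography
size exclusion
gel filtration
gel filtration chromatography
analytical ultracentrifugation
ultracentrifugation
sedimentation equilibrium
sedimentation velocity
light scattering
static light scattering
dynamic light scattering
multi angle light scattering
native page
native gel
native gel electrophoresis
native mass spectrometry
cross linking
crosslinking
small angle x ray scattering
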