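# PLACEHOLDER whitelist of alpaca VHH germline genes.
#
# WARNING: this is a PARTIAL list containing only the handful of VHH germline
# gene names that are publicly well known.  The classical/non-classical
# decision falls back to this whitelist when the FR2 hallmark residues are
# absent, so an incomplete list under-calls classical VHHs.  Substitute your
# own curated list (17 genes for alpaca) before analyzing real repertoires.
IGHV3S53*01
IGHV3-3*01
IGHV3S65*01
IGHV3S61*01
IGHV3S66*01
IGHV3S68*01
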