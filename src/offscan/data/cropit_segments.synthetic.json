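{
 "provenance": "SYNTHETIC representative CROP-IT-style segment weights: the 20-nt protospacer split into three contiguous segments with weight increasing toward the PAM-proximal seed. Segment boundaries and weights in the published method differ between descriptions; substitute transcribed values via ScoreTables.from_files if exact agreement with the original webtool is required.",
 "schema_version": 1,
 "segments": [
  {
   "end": 7,
   "start": 1,
   "weight": 15.0
  },
  {
   "end": 14,
   "start": 8,
   "weight": 30.0
  },
  {
   "end": 20,
   "start": 15,
   "weight": 55.0
  }
 ]
}
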