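{
 "tmh1": [
  15,
  40
 ],
 "tmh2": [
  45,
  70
 ],
 "heme_patch": [
  80,
  96
 ],
 "cua1": [
  160,
  176
 ],
 "cua2": [
  195,
  211
 ]
}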