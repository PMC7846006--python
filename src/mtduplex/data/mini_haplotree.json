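{
 "rCRS": {
  "parent": null,
  "snps": []
 },
 "R": {
  "parent": "rCRS",
  "snps": [
   "73A>G",
   "2706A>G",
   "7028C>T",
   "11719G>A",
   "14766C>T"
  ]
 },
 "N1": {
  "parent": "R",
  "snps": [
   "199T>C",
   "204T>C",
   "10238T>C",
   "16223C>T"
  ]
 },
 "I": {
  "parent": "N1",
  "snps": [
   "203G>A",
   "1719G>A",
   "10034T>C",
   "16129G>A",
   "16391G>A"
  ]
 },
 "I1": {
  "parent": "I",
  "snps": [
   "3447A>G",
   "6734G>A",
   "9947G>A",
   "13780A>G"
  ]
 },
 "I1a": {
  "parent": "I1",
  "snps": [
   "3990C>T",
   "12501G>A",
   "15924A>G"
  ]
 },
 "I1a1": {
  "parent": "I1a",
  "snps": [
   "4529A>T",
   "8251G>A",
   "16172T>C"
  ]
 },
 "I1a1b": {
  "parent": "I1a1",
  "snps": [
   "10398A>G",
   "10915T>C",
   "12705C>T",
   "14182T>C",
   "15043G>A",
   "16311T>C"
  ]
 },
 "U": {
  "parent": "R",
  "snps": [
   "263A>G",
   "11467A>G",
   "12308A>G",
   "12372G>A"
  ]
 },
 "U2": {
  "parent": "U",
  "snps": [
   "152T>C",
   "217T>C",
   "508A>G",
   "16051A>G",
   "16129G>C"
  ]
 },
 "U2e": {
  "parent": "U2",
  "snps": [
   "195T>C",
   "1811A>G",
   "3720A>G",
   "5426T>C",
   "6045C>T",
   "13734T>C"
  ]
 },
 "U2e2": {
  "parent": "U2e",
  "snps": [
   "3849G>A",
   "6152T>C",
   "10876A>G",
   "15907A>G"
  ]
 },
 "U2e2a": {
  "parent": "U2e2",
  "snps": [
   "4553T>C",
   "5390A>G",
   "8473T>C",
   "16189T>C",
   "16362T>C"
  ]
 },
 "U2e2a1": {
  "parent": "U2e2a",
  "snps": [
   "4736T>C",
   "12557C>T",
   "13020T>C"
  ]
 },
 "H": {
  "parent": "rCRS",
  "snps": [
   "263A>G"
  ]
 },
 "H7": {
  "parent": "H",
  "snps": [
   "4793A>G"
  ]
 },
 "H7b": {
  "parent": "H7",
  "snps": [
   "5348C>T"
  ]
 }
}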