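{
 "order": [
  "chi1",
  "chi2",
  "chi3",
  "chi2p",
  "chi1p"
 ],
 "classes": {
  "-----": "-LHSpiral",
  "----+": "+/-LHSpiral",
  "---+-": "-LHHook",
  "---++": "+/-LHHook",
  "--+--": "-RHStaple",
  "--+-+": "+/-RHStaple",
  "--++-": "-RHHook",
  "--+++": "-/+RHHook",
  "-+---": "-LHHook",
  "-+--+": "-/+LHHook",
  "-+-+-": "-LHStaple",
  "-+-++": "+/-LHStaple",
  "-++--": "-RHHook",
  "-++-+": "+/-RHHook",
  "-+++-": "-RHSpiral",
  "-++++": "+/-RHSpiral",
  "+----": "+/-LHSpiral",
  "+---+": "+LHSpiral",
  "+--+-": "-/+LHHook",
  "+--++": "+LHHook",
  "+-+--": "+/-RHStaple",
  "+-+-+": "+RHStaple",
  "+-++-": "+/-RHHook",
  "+-+++": "+RHHook",
  "++---": "+/-LHHook",
  "++--+": "+LHHook",
  "++-+-": "+/-LHStaple",
  "++-++": "+LHStaple",
  "+++--": "-/+RHHook",
  "+++-+": "+RHHook",
  "++++-": "+/-RHSpiral",
  "+++++": "+RHSpiral"
 }
}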