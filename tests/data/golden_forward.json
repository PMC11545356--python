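{
 "probs": [
  [
   0.999999999848372,
   1.516280064777496e-10
  ]
 ],
 "ap_scores_head": [
  10.600147247314453,
  5.831583023071289,
  10.835916519165039,
  7.586923599243164,
  13.478982925415039
 ],
 "la_delta_100": [
  15.364684104919434,
  -4.801223278045654,
  3.5082879066467285,
  -7.247437477111816,
  -1.2478587627410889
 ]
}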