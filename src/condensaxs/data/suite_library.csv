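name,delta_prev,epsilon,zeta,alpha,beta,gamma,delta,chi_prev,chi,pucker_prev,pucker
1a,81,-148,-71,-65,174,54,81,-158,-158,18,18
1m,84,-142,-68,-68,-138,54,84,-158,-155,18,18
1L,86,-115,-92,-56,138,62,79,-160,-158,18,18
&a,82,-169,-95,-64,-178,51,82,-158,-159,18,18
7a,84,-164,-90,65,174,54,84,-157,-158,18,18
3a,86,-148,-71,-150,170,54,85,-158,-156,18,18
9a,83,-150,-70,-60,177,172,85,-158,-160,18,18
1g,81,-141,-69,167,160,51,85,-158,-157,18,18
7d,84,-121,-103,70,170,53,85,-156,-158,18,18
3d,85,-116,-88,-155,169,53,86,-158,-158,18,18
5d,80,-158,63,68,143,50,83,-159,-158,18,18
1e,81,-159,-79,-111,83,168,86,-158,-155,18,18
1c,80,-167,-165,-69,153,54,85,-160,-158,18,18
1f,81,-160,-156,49,147,50,82,-158,-158,18,18
5j,87,-136,-146,53,-145,51,84,-155,-158,18,18
1b,84,-145,-71,-60,177,58,145,-158,-118,18,162
1[,83,-140,-71,-63,-138,54,144,-158,-120,18,162
3b,85,-134,-68,-156,174,58,148,-157,-116,18,162
1z,83,-154,-82,-164,-144,51,145,-158,-118,18,162
5z,83,-154,53,164,148,50,148,-158,-117,18,162
7p,84,-123,-140,68,-160,54,146,-156,-118,18,162
1t,81,-161,-71,-60,164,54,146,-158,-119,18,162
2a,145,-100,-71,-72,-167,53,84,-118,-158,162,18
4a,146,-100,170,-62,170,51,84,-118,-157,162,18
0a,149,-137,139,-75,158,48,84,-117,-158,162,18
#a,148,-168,146,-71,151,42,85,-118,-158,162,18
4g,148,-103,165,-155,165,49,83,-119,-158,162,18
6g,145,-97,80,-156,-170,58,85,-118,-156,162,18
8d,149,-89,-119,62,176,54,87,-118,-158,162,18
4d,150,-110,-172,-156,170,54,85,-120,-158,162,18
6d,147,-119,89,59,161,52,83,-118,-159,162,18
2h,148,-99,-70,-64,177,176,87,-118,-158,162,18
4n,144,-133,-156,74,-143,55,86,-117,-158,162,18
2[,146,-101,-69,-68,-150,54,148,-118,-118,162,162
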