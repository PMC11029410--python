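sex,age_lo,pop,acm
female,20,9388010.199547268,0.003
female,25,7496478.40621695,0.004257202645779772
female,30,5986059.59094368,0.00604125812241143
female,35,4779965.669828651,0.008572953354189491
female,40,3816880.112471207,0.012165599900534027
female,45,3047840.6748683737,0.017263808028017195
female,50,2433750.2110769222,0.02449850973770295
female,55,1943389.0159539795,0.03476504015767017
female,60,1551827.6485980784,0.049333940313291164
female,65,1239159.546124793,0.07000819374282817
female,70,989488.9952111552,0.09934635587607699
female,75,790123.010960027,0.1409791896947379
female,80,630926.0390665748,0.20005899312277547
female,85,503804.67503227224,0.28389722494477243
female,90,402296.2041000667,0.4028693390548066
male,20,9388010.199547268,0.00345
male,25,7496478.40621695,0.004895783042646738
male,30,5986059.59094368,0.006947446840773144
male,35,4779965.669828651,0.009858896357317914
male,40,3816880.112471207,0.01399043988561413
male,45,3047840.6748683737,0.019853379232219772
male,50,2433750.2110769222,0.028173286198358388
male,55,1943389.0159539795,0.03997979618132069
male,60,1551827.6485980784,0.056734031360284834
male,65,1239159.546124793,0.08050942280425238
male,70,989488.9952111552,0.11424830925748852
male,75,790123.010960027,0.1621260681489486
male,80,630926.0390665748,0.23006784209119177
male,85,503804.67503227224,0.3264818086864883
male,90,402296.2041000667,0.46329973991302753
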