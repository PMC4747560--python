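mode,classifier,normalization,statistic,sigma,emotion,rate_percent
MD,KNN,none,mean,,anger,93.33
MD,KNN,none,mean,,disgust,80.83
MD,KNN,none,mean,,fear,95.83
MD,KNN,none,mean,,sadness,76.67
MD,KNN,none,mean,,happiness,90.00
MD,KNN,none,mean,,surprise,90.00
MD,KNN,none,rms,,anger,89.17
MD,KNN,none,rms,,disgust,84.17
MD,KNN,none,rms,,fear,86.67
MD,KNN,none,rms,,sadness,85.83
MD,KNN,none,rms,,happiness,95.00
MD,KNN,none,rms,,surprise,93.33
MD,KNN,none,variance,,anger,45.00
MD,KNN,none,variance,,disgust,55.83
MD,KNN,none,variance,,fear,55.00
MD,KNN,none,variance,,sadness,49.17
MD,KNN,none,variance,,happiness,49.17
MD,KNN,none,variance,,surprise,63.33
MD,KNN,binary,mean,,anger,87.50
MD,KNN,binary,mean,,disgust,80.00
MD,KNN,binary,mean,,fear,89.17
MD,KNN,binary,mean,,sadness,89.17
MD,KNN,binary,mean,,happiness,86.67
MD,KNN,binary,mean,,surprise,90.83
MD,KNN,binary,rms,,anger,85.00
MD,KNN,binary,rms,,disgust,81.67
MD,KNN,binary,rms,,fear,87.50
MD,KNN,binary,rms,,sadness,84.17
MD,KNN,binary,rms,,happiness,81.67
MD,KNN,binary,rms,,surprise,94.17
MD,KNN,binary,variance,,anger,45.83
MD,KNN,binary,variance,,disgust,57.50
MD,KNN,binary,variance,,fear,47.50
MD,KNN,binary,variance,,sadness,50.00
MD,KNN,binary,variance,,happiness,47.50
MD,KNN,binary,variance,,surprise,51.67
MD,KNN,bipolar,mean,,anger,85.83
MD,KNN,bipolar,mean,,disgust,86.67
MD,KNN,bipolar,mean,,fear,83.33
MD,KNN,bipolar,mean,,sadness,91.67
MD,KNN,bipolar,mean,,happiness,84.17
MD,KNN,bipolar,mean,,surprise,92.50
MD,KNN,bipolar,rms,,anger,87.50
MD,KNN,bipolar,rms,,disgust,84.17
MD,KNN,bipolar,rms,,fear,86.67
MD,KNN,bipolar,rms,,sadness,85.00
MD,KNN,bipolar,rms,,happiness,91.67
MD,KNN,bipolar,rms,,surprise,91.67
MD,KNN,bipolar,variance,,anger,47.50
MD,KNN,bipolar,variance,,disgust,55.83
MD,KNN,bipolar,variance,,fear,51.67
MD,KNN,bipolar,variance,,sadness,43.33
MD,KNN,bipolar,variance,,happiness,45.83
MD,KNN,bipolar,variance,,surprise,55.83
CMD,PNN,none,mean,0.02,anger,100.00
CMD,PNN,none,mean,0.02,disgust,82.50
CMD,PNN,none,mean,0.02,fear,88.33
CMD,PNN,none,mean,0.02,sadness,81.67
CMD,PNN,none,mean,0.02,happiness,88.33
CMD,PNN,none,mean,0.02,surprise,90.00
CMD,PNN,none,rms,0.02,anger,100.00
CMD,PNN,none,rms,0.02,disgust,81.67
CMD,PNN,none,rms,0.02,fear,90.00
CMD,PNN,none,rms,0.02,sadness,74.17
CMD,PNN,none,rms,0.02,happiness,93.33
CMD,PNN,none,rms,0.02,surprise,93.33
CMD,PNN,none,variance,0.02,anger,81.67
CMD,PNN,none,variance,0.02,disgust,82.50
CMD,PNN,none,variance,0.02,fear,80.00
CMD,PNN,none,variance,0.02,sadness,78.33
CMD,PNN,none,variance,0.02,happiness,90.00
CMD,PNN,none,variance,0.02,surprise,78.33
CMD,PNN,binary,mean,0.08,anger,79.17
CMD,PNN,binary,mean,0.08,disgust,86.67
CMD,PNN,binary,mean,0.08,fear,95.00
CMD,PNN,binary,mean,0.08,sadness,90.83
CMD,PNN,binary,mean,0.08,happiness,98.33
CMD,PNN,binary,mean,0.08,surprise,98.33
CMD,PNN,binary,rms,0.07,anger,87.50
CMD,PNN,binary,rms,0.07,disgust,94.17
CMD,PNN,binary,rms,0.07,fear,95.00
CMD,PNN,binary,rms,0.07,sadness,82.50
CMD,PNN,binary,rms,0.07,happiness,98.33
CMD,PNN,binary,rms,0.07,surprise,100.00
CMD,PNN,binary,variance,0.01,anger,39.17
CMD,PNN,binary,variance,0.01,disgust,55.83
CMD,PNN,binary,variance,0.01,fear,65.83
CMD,PNN,binary,variance,0.01,sadness,47.50
CMD,PNN,binary,variance,0.01,happiness,82.50
CMD,PNN,binary,variance,0.01,surprise,45.83
CMD,PNN,bipolar,mean,0.09,anger,69.17
CMD,PNN,bipolar,mean,0.09,disgust,80.00
CMD,PNN,bipolar,mean,0.09,fear,86.67
CMD,PNN,bipolar,mean,0.09,sadness,89.17
CMD,PNN,bipolar,mean,0.09,happiness,98.33
CMD,PNN,bipolar,mean,0.09,surprise,97.50
CMD,PNN,bipolar,rms,0.09,anger,98.33
CMD,PNN,bipolar,rms,0.09,disgust,96.67
CMD,PNN,bipolar,rms,0.09,fear,98.33
CMD,PNN,bipolar,rms,0.09,sadness,89.17
CMD,PNN,bipolar,rms,0.09,happiness,99.17
CMD,PNN,bipolar,rms,0.09,surprise,100.00
CMD,PNN,bipolar,variance,0.01,anger,54.17
CMD,PNN,bipolar,variance,0.01,disgust,75.83
CMD,PNN,bipolar,variance,0.01,fear,69.17
CMD,PNN,bipolar,variance,0.01,sadness,56.67
CMD,PNN,bipolar,variance,0.01,happiness,87.50
CMD,PNN,bipolar,variance,0.01,surprise,62.50
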