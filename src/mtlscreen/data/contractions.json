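{
  "i'm": "i am",
  "i've": "i have",
  "i'll": "i will",
  "i'd": "i would",
  "you're": "you are",
  "you've": "you have",
  "you'll": "you will",
  "you'd": "you would",
  "he's": "he is",
  "he'll": "he will",
  "he'd": "he would",
  "she's": "she is",
  "she'll": "she will",
  "she'd": "she would",
  "it's": "it is",
  "it'll": "it will",
  "it'd": "it would",
  "we're": "we are",
  "we've": "we have",
  "we'll": "we will",
  "we'd": "we would",
  "they're": "they are",
  "they've": "they have",
  "they'll": "they will",
  "they'd": "they would",
  "that's": "that is",
  "that'll": "that will",
  "that'd": "that would",
  "there's": "there is",
  "there'll": "there will",
  "there'd": "there would",
  "here's": "here is",
  "what's": "what is",
  "what're": "what are",
  "what'll": "what will",
  "who's": "who is",
  "who're": "who are",
  "who'll": "who will",
  "where's": "where is",
  "when's": "when is",
  "why's": "why is",
  "how's": "how is",
  "let's": "let us",
  "ain't": "is not",
  "aren't": "are not",
  "isn't": "is not",
  "wasn't": "was not",
  "weren't": "were not",
  "don't": "do not",
  "doesn't": "does not",
  "didn't": "did not",
  "can't": "cannot",
  "couldn't": "could not",
  "won't": "will not",
  "wouldn't": "would not",
  "shan't": "shall not",
  "shouldn't": "should not",
  "mightn't": "might not",
  "mustn't": "must not",
  "haven't": "have not",
  "hasn't": "has not",
  "hadn't": "had not",
  "needn't": "need not",
  "could've": "could have",
  "would've": "would have",
  "should've": "should have",
  "might've": "might have",
  "must've": "must have",
  "o'clock": "of the clock",
  "y'all": "you all",
  "gonna": "going to",
  "gotta": "got to",
  "wanna": "want to"
}
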