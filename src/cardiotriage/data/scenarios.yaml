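# Bundled usability-test workflow: five scripted scenarios behind one menu.
# Entry points: s1_start (sign-in and event profile), s2_start (heart check),
# s3_start (wellness check), s4_start (library), s5_start (on-demand heart
# check, which routes into the heart-check chain).
start: menu
states:
  menu:
    prompts:
      - "Hi, I'm Holly. Which scenario would you like to run?"
    input:
      type: choice
      options: [scenario1, scenario2, scenario3, scenario4, scenario5]
    transitions:
      scenario1: s1_start
      scenario2: s2_start
      scenario3: s3_start
      scenario4: s4_start
      scenario5: s5_start

  # --- scenario 1: sign-in, chatbot introduction, event profile ---
  s1_start:
    prompts:
      - "Welcome! Before we begin: I'm a chatbot, not a real person. I was designed by a team of women's heart health experts to help you track and understand your heart pain through regular check-ins."
      - "Let's build your Event Profile: a record of the pain you felt during your cardiac event."
    next: s1_quality
  s1_quality:
    prompts:
      - "How would you describe the quality of that pain? (for example: heavy, tight, pressure)"
    input: {type: text}
    transitions: {"*": s1_location}
  s1_location:
    prompts:
      - "Where on your body did you feel it? Pick the closest region on the body map."
    input: {type: text}
    transitions: {"*": s1_confirm}
  s1_confirm:
    prompts:
      - "Thanks. Shall I save this as your Event Profile?"
    input: {type: yes_no}
    transitions: {yes: s1_saved, no: s1_quality}
  s1_saved:
    prompts:
      - "Your Event Profile is saved. I'll compare every Heart Check against it."
    next: done

  # --- scenario 2: chatbot-guided heart check ---
  s2_start:
    activity: heart_check
    prompts:
      - "Time for a Heart Check. I'll ask the same short set of questions each time."
      - "Have you had any heart pain or discomfort since we last spoke?"
    input: {type: yes_no}
    transitions: {yes: s2_quality, no: s2_none}
  s2_none:
    prompts:
      - "Great news. No similar or high-risk symptoms means you're in the green: keep using the app as usual."
    next: done
  s2_quality:
    prompts:
      - "I'm sorry to hear that. What did the pain feel like? (dull, heavy, tight, pressure, sharp, or burning)"
    input: {type: text}
    transitions: {"*": s2_when}
  s2_when:
    prompts:
      - "How many hours ago did it start? (0 to 720)"
    input: {type: int, min: 0, max: 720}
    reprompt: "Please give the number of hours ago it started, between 0 and 720."
    transitions: {"*": s2_done}
  s2_done:
    prompts:
      - "Thank you. I'll compare this with your Event Profile and recommend the right level of care."
    next: done

  # --- scenario 3: wellness check (7 domains, 0-10 each) ---
  s3_start:
    activity: wellness_check
    prompts:
      - "Let's do your weekly Wellness Check: 7 quick questions, each scored 0 (worst) to 10 (best)."
    next: s3_q1
  s3_q1:
    prompts: ["How is your general activity?"]
    input: {type: int, min: 0, max: 10}
    reprompt: "Please answer with a whole number from 0 to 10."
    transitions: {"*": s3_q2}
  s3_q2:
    prompts: ["How is your paid and unpaid work going?"]
    input: {type: int, min: 0, max: 10}
    reprompt: "Please answer with a whole number from 0 to 10."
    transitions: {"*": s3_q3}
  s3_q3:
    prompts: ["How is your walking?"]
    input: {type: int, min: 0, max: 10}
    reprompt: "Please answer with a whole number from 0 to 10."
    transitions: {"*": s3_q4}
  s3_q4:
    prompts: ["How is your mood?"]
    input: {type: int, min: 0, max: 10}
    reprompt: "Please answer with a whole number from 0 to 10."
    transitions: {"*": s3_q5}
  s3_q5:
    prompts: ["How are your relations with others?"]
    input: {type: int, min: 0, max: 10}
    reprompt: "Please answer with a whole number from 0 to 10."
    transitions: {"*": s3_q6}
  s3_q6:
    prompts: ["How is your sleep?"]
    input: {type: int, min: 0, max: 10}
    reprompt: "Please answer with a whole number from 0 to 10."
    transitions: {"*": s3_q7}
  s3_q7:
    prompts: ["How is your overall enjoyment of life?"]
    input: {type: int, min: 0, max: 10}
    reprompt: "Please answer with a whole number from 0 to 10."
    transitions: {"*": s3_done}
  s3_done:
    prompts:
      - "Thanks. Based on what you've told me, I'll pick out library topics for any domain you scored 4 or lower."
    next: done

  # --- scenario 4: browsing the library ---
  s4_start:
    prompts:
      - "The library has scientific papers with lay summaries, videos, and podcasts. Want me to open it?"
    input: {type: yes_no}
    transitions: {yes: s4_open, no: done}
  s4_open:
    prompts:
      - "Here you go. You can browse anytime, anywhere."
    next: done

  # --- scenario 5: on-demand heart check request ---
  s5_start:
    prompts:
      - "You can ask me for a Heart Check at any time, not just every 3 days. Would you like one now?"
    input: {type: yes_no}
    transitions: {yes: s2_start, no: done}

  done:
    prompts:
      - "That's all for now. Take care — I'll check in with you again soon."
    terminal: true
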